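"""Haul-level survey records: domain types, validation, CSV round-trip, filters.

The atomic observation is one seine haul: where and when it happened, the
water-column covariates measured alongside it, the total catch, and a
subsample of up to ten standard lengths (mm).  Hauls closer than 5 m to the
shoreline are excluded from analysis; that filter lives here so every
downstream stage sees the same record set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError, ValidationError

#: Exact CSV header, in order.  ``lengths_mm`` is a semicolon-separated list.
HAUL_COLUMNS = [
    "haul_id",
    "estuary",
    "year",
    "month",
    "area_swept_m2",
    "depth_m",
    "temperature_c",
    "salinity",
    "sav_pct",
    "shore_distance_m",
    "count",
    "lengths_mm",
]

#: Default estuary codes (Apalachicola Bay, Cedar Key, Tampa Bay, Charlotte Harbor).
DEFAULT_ESTUARIES = ("AB", "CK", "TB", "CH")

#: Swept area of one standard 21.3 m center-bag seine haul.
DEFAULT_AREA_SWEPT_M2 = 140.0

#: Maximum number of individuals measured per haul.
MAX_MEASURED = 10


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(eq=False)
class HaulRecord:
    """One seine haul with environment, total count, and measured lengths."""

    haul_id: str
    estuary: str
    year: int
    month: int
    area_swept_m2: float
    depth_m: float
    temperature_c: float
    salinity: float
    sav_pct: float
    shore_distance_m: float
    count: int
    lengths_mm: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.lengths_mm = tuple(float(v) for v in self.lengths_mm)
        self.validate()

    def validate(self, row=None):
        if not (1 <= int(self.month) <= 12):
            raise ValidationError(f"month {self.month} not in 1..12", row)
        if not self.area_swept_m2 > 0:
            raise ValidationError(f"area_swept_m2 {self.area_swept_m2} must be > 0", row)
        if int(self.count) < 0:
            raise ValidationError(f"count {self.count} must be >= 0", row)
        if len(self.lengths_mm) > MAX_MEASURED:
            raise ValidationError(
                f"{len(self.lengths_mm)} measured lengths exceed the {MAX_MEASURED}-fish subsample",
                row,
            )
        if len(self.lengths_mm) > int(self.count):
            raise ValidationError(
                f"count={self.count} but {len(self.lengths_mm)} measured lengths", row
            )
        if not _is_missing(self.sav_pct):
            sav = float(self.sav_pct)
            if not (0 <= sav <= 100) or sav % 10 != 0:
                raise ValidationError(
                    f"sav_pct {self.sav_pct} must be a multiple of 10 in [0, 100]", row
                )
        if not _is_missing(self.shore_distance_m) and self.shore_distance_m < 0:
            raise ValidationError(
                f"shore_distance_m {self.shore_distance_m} must be >= 0", row
            )
        if any(v <= 0 for v in self.lengths_mm):
            raise ValidationError("standard lengths must be positive", row)

    def __eq__(self, other):
        # NaN-valued environmental fields compare equal so that CSV
        # round-trips of records with missing covariates are lossless.
        if not isinstance(other, HaulRecord):
            return NotImplemented
        for name in self.__dataclass_fields__:
            a, b = getattr(self, name), getattr(other, name)
            if isinstance(a, float) and isinstance(b, float):
                if not (a == b or (math.isnan(a) and math.isnan(b))):
                    return False
            elif a != b:
                return False
        return True


@dataclass
class LengthWeightParams:
    """Allometric length-weight constants W = a * SL**b for one estuary."""

    estuary: str
    a: float
    b: float

    def __post_init__(self):
        if not self.a > 0 or not self.b > 0:
            raise ValidationError(f"length-weight constants must be positive: a={self.a}, b={self.b}")


class HaulTable:
    """Ordered collection of :class:`HaulRecord` with unique ``haul_id``."""

    def __init__(self, records, provenance: str = ""):
        self.records = list(records)
        self.provenance = provenance
        seen = set()
        for i, r in enumerate(self.records):
            if r.haul_id in seen:
                raise ValidationError(f"duplicate haul_id {r.haul_id!r}", i)
            seen.add(r.haul_id)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other):
        return isinstance(other, HaulTable) and self.records == other.records

    def to_dataframe(self) -> pd.DataFrame:
        """One row per haul; ``lengths_mm`` serialized as ``"42;57;61"``."""
        rows = []
        for r in self.records:
            d = {c: getattr(r, c) for c in HAUL_COLUMNS if c != "lengths_mm"}
            d["lengths_mm"] = ";".join(_fmt_len(v) for v in r.lengths_mm)
            rows.append(d)
        return pd.DataFrame(rows, columns=HAUL_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "HaulTable":
        missing = [c for c in HAUL_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            records.append(_record_from_row(row._asdict(), i))
        return cls(records, provenance=provenance)


def _fmt_len(v: float) -> str:
    # shortest lossless decimal representation
    s = repr(float(v))
    return s[:-2] if s.endswith(".0") else s


def _parse_lengths(cell) -> tuple:
    if _is_missing(cell) or str(cell).strip() == "":
        return ()
    return tuple(float(tok) for tok in str(cell).split(";"))


def _record_from_row(d: dict, row_index: int) -> HaulRecord:
    try:
        count = d["count"]
        if _is_missing(count):
            raise ValidationError("count is mandatory", row_index)
        fcount = float(count)
        if fcount != int(fcount):
            raise ValidationError(f"non-integer count {count!r}", row_index)
        rec = HaulRecord(
            haul_id=str(d["haul_id"]),
            estuary=str(d["estuary"]),
            year=int(d["year"]),
            month=int(d["month"]),
            area_swept_m2=float(d["area_swept_m2"]),
            depth_m=_float_or_nan(d["depth_m"]),
            temperature_c=_float_or_nan(d["temperature_c"]),
            salinity=_float_or_nan(d["salinity"]),
            sav_pct=_float_or_nan(d["sav_pct"]),
            shore_distance_m=_float_or_nan(d["shore_distance_m"]),
            count=int(fcount),
            lengths_mm=_parse_lengths(d["lengths_mm"]),
        )
    except ValidationError as exc:
        if exc.row is None:
            raise ValidationError(str(exc), row_index) from exc
        raise
    except (TypeError, ValueError) as exc:
        raise ValidationError(str(exc), row_index) from exc
    return rec


def _float_or_nan(x) -> float:
    if _is_missing(x) or str(x).strip() == "":
        return float("nan")
    return float(x)


def read_hauls(path, provenance: str | None = None) -> HaulTable:
    """Read a haul CSV (documented schema) into a validated :class:`HaulTable`.

    Malformed rows raise :class:`ValidationError` carrying the 0-based data
    row number; a missing mandatory column raises :class:`SchemaError`.
    """
    df = pd.read_csv(
        path,
        dtype={"haul_id": str, "estuary": str, "lengths_mm": str},
        float_precision="round_trip",
    )
    return HaulTable.from_dataframe(df, provenance=provenance or str(path))


def write_hauls(table: HaulTable, path) -> None:
    """Write a HaulTable to CSV, losslessly re-readable by :func:`read_hauls`."""
    df = table.to_dataframe()
    df.to_csv(path, index=False)


def filter_hauls(table: HaulTable, min_shore_distance: float = 5.0) -> HaulTable:
    """Keep hauls at least ``min_shore_distance`` m from the shoreline.

    Hauls with a missing shore distance are dropped (distance unknown, the
    inclusion rule cannot be verified).  Order is preserved; idempotent.
    """
    if min_shore_distance < 0:
        raise ValueError("min_shore_distance must be >= 0")
    kept = [
        r
        for r in table.records
        if not _is_missing(r.shore_distance_m) and r.shore_distance_m >= min_shore_distance
    ]
    return HaulTable(kept, provenance=table.provenance)


def read_length_weight(path) -> dict:
    """Read a CSV ``estuary,a,b`` into a dict of :class:`LengthWeightParams`."""
    df = pd.read_csv(path)
    for c in ("estuary", "a", "b"):
        if c not in df.columns:
            raise SchemaError(f"length-weight file missing column {c!r}")
    return {
        str(r.estuary): LengthWeightParams(str(r.estuary), float(r.a), float(r.b))
        for r in df.itertuples(index=False)
    }


def write_length_weight(params: dict, path) -> None:
    df = pd.DataFrame(
        [(p.estuary, p.a, p.b) for p in params.values()], columns=["estuary", "a", "b"]
    )
    df.to_csv(path, index=False)
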
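# pinfish

Population-dynamics analysis of an estuarine forage fish (Pinfish,
*Lagodon rhomboides*) from fisheries-independent seine-survey data, built
as a tested, reusable pipeline with a synthetic survey generator standing
in for the undeposited monitoring records.

Monthly stratified seine surveys (140 m² swept per haul, up to ten
standard lengths measured per haul) across four Gulf-coast estuaries —
Apalachicola Bay (AB), Cedar Key (CK), Tampa Bay (TB) and Charlotte
Harbor (CH) — support five linked analyses:

1. **Abundance.** Haul density `100·count/area` (fish/100 m²) and biomass
   via the allometric length–weight relationship `W = a·SL^b`, with the
   mean measured weight extrapolated to the unmeasured catch; monthly
   means ± SE, 12-month climatologies (intra-annual signal), monthly
   anomalies (inter-annual signal), and annual/long-term standardized
   ratios.
2. **Synchrony.** Lagged cross-correlation between estuary pairs at lags
   0–3 months: detrended (month-standardized) anomalies for inter-annual
   synchrony, circularly shifted climatologies for intra-annual synchrony,
   with a white-noise significance bound adjusted for the lag search.
3. **Portfolio effects.** The average-CV portfolio effect for a
   metapopulation of n local populations,

       CVPE = [(CV_p1 + … + CV_pn)/n] / CV_m ,

   where local and metapopulation CVs are taken over annual peaks of the
   3-month moving average. CVPE = 1 marks a single homogeneous population;
   values above 1 quantify variance dampening from asynchrony (for n
   mutually independent populations CVPE → √n).
4. **Cohort growth.** December standard-length samples are tested for the
   bimodality created by newly settled recruits — bimodality coefficient
   `(g₁²+1)/(g₂+3(n−1)²/((n−2)(n−3))) > 5/9` *and* Hartigan's dip test
   (Monte-Carlo p against uniform nulls) — then split at the
   kernel-density antimode into a "month 0" recruit cohort. Instantaneous
   growth follows `ln L_t = ln L₀ + G·t` (G per month), fitted by OLS on
   April–July mean lengths.
5. **Habitat model.** A zero-altered (hurdle) negative binomial GLM of
   haul counts: logistic presence part and zero-truncated NB count part
   (log link, ln-area offset) on SAV cover, temperature, salinity, depth,
   SAV² and SAV×temperature, all z-scored so coefficients are
   standardized; stepwise AIC term selection, VIF/tolerance collinearity
   diagnostics, and AIC comparison against ZAP/ZINB/ZIP alternatives.

The dip statistic is implemented from first principles (greatest-convex-
minorant / least-concave-majorant band feasibility over candidate modal
points) and verified against an exhaustive search and a linear-program
formulation; the hurdle and zero-inflated likelihoods are maximised
directly and cross-checked against independent implementations in the
test suite.

## Worked example

```python
from pinfish import (simulate_survey, filter_hauls, monthly_mean,
                     fit_growth, monthly_mean_lengths, split_december_cohort)
from pinfish.simulate import MetapopConfig
from pinfish.portfolio import cvpe

table, truth = simulate_survey(MetapopConfig(seed=1))   # 13,255 hauls
table = filter_hauls(table)                             # 11,624 ≥ 5 m from shore
dens = monthly_mean(table)                              # per-estuary series

print(cvpe([dens[e] for e in ("AB", "CK", "TB", "CH")], "full").summary())
```

```
Portfolio 'full': members AB, CK, TB, CH
  CV[AB] = 0.5907
  CV[CK] = 0.4904
  CV[TB] = 0.7003
  CV[CH] = 0.5988
  CV[metapopulation] = 0.4954
  CVPE = 1.2012
```

Local annual-peak densities vary with CVs of 0.49–0.70; averaging the four
estuaries dampens that variation (CV 0.50), so the metapopulation is ~20%
more stable than a single homogeneous population would be
(`CVPE = 1.20 > 1`).

```python
g = fit_growth(monthly_mean_lengths(table, estuary="CH"), estuary="CH")
print(g.summary())
```

```
Instantaneous growth, estuary CH
  G  = 0.1652 per month (SE 0.0052)
  L0 = 13.58 mm at recruitment (t = 0, December)
  R^2 = 0.9981; months used: (4, 5, 6, 7)
```

The generator's truth is `G = 0.16`, `L0 = 14 mm`; the April–July fit
recovers both. The December cohort gate on the same survey
(`split_december_cohort`) reports `bc = 0.91 > 5/9`, dip `0.162`
(p = 5×10⁻⁴), and splits recruits from residents at 55.1 mm.

The same pipeline runs from the shell:

```bash
popdyn run --out-dir results --seed 1      # simulate + all analyses + report.md
popdyn simulate --out hauls.csv --seed 1   # just the synthetic survey
popdyn habitat --hauls hauls.csv           # just the hurdle habitat models
```

Every run writes CSV artifacts (monthly series, climatologies, synchrony
panels, portfolio table, cohort/growth tables, habitat coefficients,
model comparison, VIF) plus a manifest of SHA-256 hashes; identical
config and seed reproduce byte-identical artifacts.

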
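# mrrkit

Analysis toolkit for mark-release-recapture (MRR) studies of butterflies
and other short-lived insects, built around the workflow used to compare
the two annual generations of a bivoltine species: open-population
abundance estimation, dispersal-kernel fitting with long-distance
extrapolation, and behaviour / wing-condition statistics — plus a seeded
synthetic-data generator so every stage can be tested against known truth.

## What it computes

**Abundance (POPAN).** Daily and total population sizes come from the
Schwarz–Arnason superpopulation parameterization of the Jolly–Seber model.
A sex group has `N` individuals in total; each enters the study area just
before occasion *b* with probability `pent_b` (a simplex over occasions),
survives occasion-to-occasion with probability `phi`, and is detected with
probability `p`. Model structures are written in the standard shorthand,
e.g.

```
Phi(g+T^2) p(g+t) pent(g*T^2) N(g)
```

with `.` constant, `g` sex, `t` factorial time, `T` / `T^2` linear /
quadratic trends, `+` additive and `*` interactive combinations, and an
optional sampling-effort covariate on `p`. Candidate models are ranked by

```
QAICc = -2 lnL / c-hat + 2K + 2K(K+1) / (n_eff - K - 1)
```

where `c-hat` is a dispersion factor (parametric bootstrap, deviance/df,
or a manually supplied value) and `n_eff` the number of marked
individuals. Estimates can be model-averaged with Akaike weights and
Buckland unconditional standard errors. Daily abundances follow
`B_t = N pent_t`, `N_{t+1} = N_t phi_t + B_{t+1}`, with delta-method SEs.

**Dispersal.** Straight-line displacements between first and second
capture (GPS positions projected to a local plane) are binned into 20 /
30 / 50 m distance classes; the inverse cumulative proportion `I` of
individuals reaching each class is fitted on the log scale with the
negative exponential function `I = a e^(-kD)` and the inverse power
function `I = c D^(-n)`. The kernel/interval combination with the highest
R² is used to extrapolate the percentage of individuals expected to move
1–5 km.

**Behaviour and condition.** Chi-squared homogeneity tests on first-record
behaviour and nectar-genus tables, daily mean wing-wear series (ordinal
1–4 scores; days with < 5 specimens excluded) with linear decay
regressions and slope-interaction F-tests, Mann–Whitney U comparisons,
and a protandry index (the offset in days between the sexes' 50%
cumulative-recruitment dates).

## Worked example

```python
from mrrkit.simulate import get_preset, simulate_mrr
from mrrkit.events import build_encounter_histories, recapture_summary
from mrrkit.popan import fit_model
from mrrkit.behaviour import protandry_index
from mrrkit.dispersal import displacement_table, select_best_fit, extrapolate_proportion

events, truth = simulate_mrr(get_preset("gen1-like", seed=1))
hist = build_encounter_histories(events)
print(recapture_summary(hist)[["group", "marked", "recaptured", "percent_recaptured"]])

fit = fit_model("Phi(.) p(g) pent(g*T^2) N(g)", hist, random_state=0)
for g, n, se in zip(fit.group_names_, fit.nhat_, fit.nhat_se_):
    print(f"N_hat {g}: {n:.0f} +- {se:.0f} (truth {truth['groups'][g]['n_super']})")

ab = fit.derived_abundance()
print(f"protandry offset: {protandry_index(ab[ab.group=='male'], ab[ab.group=='female']):.1f} days")

sel = select_best_fit(displacement_table(events))
for kind, f in sel["best"].items():
    pct = extrapolate_proportion(f, [1000.0])["percent"].iloc[0]
    print(f"{kind}: best at {f.interval_width_:.0f} m, R^2 = {f.r2_:.3f}, {pct:.2f}% reach 1 km")
```

prints

```
 group  marked  recaptured  percent_recaptured
female     120          64                  53
  male     122          73                  60
N_hat female: 171 +- 11 (truth 155)
N_hat male: 150 +- 7 (truth 155)
protandry offset: 4.3 days
NEF: best at 30 m, R^2 = 0.983, 0.01% reach 1 km
IPF: best at 50 m, R^2 = 0.791, 0.94% reach 1 km
```

The `gen1-like` preset simulates a protandrous first-generation world
(21 occasions, 155 individuals per sex); the fitted superpopulation sizes
bracket the truth within ~1.5 SE, the protandry index recovers the
4-day entry shift, and the heavier power-law tail predicts more
long-distance movement than the exponential — the qualitative signature
such field studies report.

The same pipeline runs from the shell: `mrrkit simulate`, `mrrkit
histories` (also writes MARK-style `.inp` files), `mrrkit popan`,
`mrrkit dispersal`, `mrrkit behaviour`, and `mrrkit report --config
cfg.json` for the full reproducible bundle with a run manifest.

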
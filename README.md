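# elevgrad

Analysis toolkit for **species-richness patterns along elevational
gradients**, built for two-slope small-mammal trapping surveys on a
discrete band domain but applicable to any bounded gradient sampled at
evenly spaced stations.

Montane surveys ask two questions: what shape does richness take along
the gradient (hump-shaped, increasing, decreasing?), and which of the
usual suspects — geometric constraints, area, climate, productivity,
plant richness — drives it. `elevgrad` implements the standard
quantitative chain for answering both from raw capture records:

1. **Range assembly** — per-species elevational ranges from captures,
   with the interpolation rule (a species caught at 2,000 m and 2,600 m
   is assumed present at 2,200 m and 2,400 m), and partitioning of the
   pool into taxonomic (insectivores / rodents), range-size
   (large / small, median split) and endemism groups.
2. **Mid-domain-effect (MDE) null model** — the discrete-domain null:
   hold the empirical multiset of range sizes fixed, place each range of
   size *r* uniformly over its *m − r + 1* feasible positions on the
   *m*-band domain, and tally per-band richness. Because boundaries
   force large ranges toward the middle, the null predicts a
   mid-elevation hump with no environmental input at all. The package
   provides both the simulation envelope (mean and 95% percentile CI
   over 5,000 draws) and the exact closed form

   E[S_j] = Σ_r (min(j, m−r+1) − max(1, j−r+1) + 1) / (m − r + 1),

   plus the conventional test of the null's explanatory power: OLS of
   observed richness on log predicted richness.
3. **Trend fits** — degree 1–3 polynomial regressions of richness on
   (centered) elevation, ranked by AICc = −2logL + 2K + 2K(K+1)/(n−K−1),
   with K counting the residual variance.
4. **Driver selection** — Pearson screen dropping all but one of any
   predictor cluster with |r| > 0.7; all-subsets fits of the global
   model `richness ~ slope * (MDE + area + NDVI + PSR)` (log-transformed
   elevational covariates, marginality enforced); best model by lowest
   AICc; model averaging over the 95% cumulative-Akaike-weight set with
   per-term summed-weight importance; VIF and Moran's *I* residual
   diagnostics.
5. **Synthetic surveys** — a seeded generator producing capture records,
   traits and covariates with the statistical structure the analysis
   assumes (contiguous ranges, Poisson abundance with binomial
   detection, covariates with realistic correlation structure), so the
   whole chain is testable end-to-end against known truth.

## Worked example

Simulate the packaged two-slope survey (6 bands at 1,800–2,800 m,
27 and 33 species, 23 shared) and run the full pipeline:

```bash
elevgrad report --seed 7 --n-sims 2000 --out demo/
# report written to demo/ (436 captures, seed 7)
```

`demo/run_log.json` then contains, among others:

```json
"mde_fits": {
  "total/west": {"r_squared": 0.860, "p_value": 0.0077},
  "total/east": {"r_squared": 0.862, "p_value": 0.0075}
},
"drivers": {
  "total": {
    "best_terms": ["MDE"],
    "best_r_squared": 0.859,
    "importance": {"MDE": 1.0, "slope": 0.093, "NDVI": 0.079, "area": 0.072}
  }
}
```

Read: on this synthetic survey — whose generator places ranges by the
mid-domain null — observed richness tracks the MDE prediction closely
(R² ≈ 0.86, p < 0.01 on both slopes), the best AICc model for total
richness contains only the MDE term, and model averaging gives MDE a
summed-weight importance of 1.0 while every environmental covariate
stays below 0.1. The machinery recovers the process that generated the
data.

Other subcommands (`simulate`, `richness`, `mde`, `polyfit`, `select`)
expose the individual stages; `--help` on each lists the options. The
same functionality is available as a library:

```python
import elevgrad as eg
pred = eg.simulate_mde([2, 3, 4, 5], m=6, n_sims=5000, seed=1)
pred.mean_richness, pred.ci_low, pred.ci_high, pred.analytic_expectation
```

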
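# honosnet

Two-arm outcome analysis for paired 12-item ordinal symptom ratings
(HoNOS-style), built for routine outcome measurement in mental-health
services.

Clinical services typically judge outcomes by how individual symptom scores
change between intake and follow-up. That view ignores how symptoms hang
together: a network of conditionally dependent symptoms can stay tightly
coupled — and a disorder self-sustaining — even while every individual score
improves. `honosnet` implements both analyses side by side for cohorts rated
twice on the 12 HoNOS items (each scored 0–4):

1. **Individual scores.** Baseline severity (any item ≥ 3) and treatment
   response (non-severe at end point); per-item paired Wilcoxon signed-rank
   tests (exact p by sign-flip enumeration for ≤ 25 nonzero differences,
   tie/continuity-corrected normal approximation beyond); logistic
   regression of response on baseline items, age and gender.
2. **Symptom networks.** Scores are residualized on the between-rating delay
   (OLS per item, per occasion); the latent correlation matrix is estimated
   with the nonparanormal SKEPTIC `r = sin(π/2·τ_b)`; a sparse Gaussian
   graphical model is fitted along a graphical-lasso path and selected by
   the extended BIC (`−2L + E·log n + 4Eγ·log p`, pipeline preset `γ = 0`);
   edges are partial correlations `w_ij = −K_ij/√(K_ii·K_jj)`. Networks are
   compared by global strength `Σ_{i<j}|w_ij|` with a permutation test
   (pooled regrouping, add-one p), and node-strength centrality is screened
   by case-drop bootstrap stability (CS-coefficient).

A synthetic-cohort generator (latent Gaussian copula over a known sparse
partial-correlation network, ordinal thresholds calibrated to realistic
item means) gives every stage a recoverable ground truth.

## Worked example

```bash
honosnet simulate --n 248 --seed 7 --out cohort.csv --truth truth.json
honosnet run cohort.csv --out report --seed 7 --n-perm 1000 --n-boots 250
```

which prints (numbers from this exact invocation):

```
wrote 248 patients to cohort.csv
done: 152 patients analysed; NCT p=0.1798; report in report
```

Of the 248 simulated patients, 152 met the baseline severity criterion and
enter the analysis (the generator's marginals make roughly 40% of screened
patients non-severe at intake, as in routine cohorts). A few values from
`report/report.json` and what they mean:

* `individual_scores.response_proportion: 0.605` — 60.5% of analysed
  patients reached the non-severe level at end point.
* `network_estimation.baseline.global_strength: 5.35` vs
  `endpoint.global_strength: 7.40` — the end-point network (generated from
  a denser truth: 32 true edges vs 13) is more strongly connected as
  estimated, though both estimates carry extra small edges (see
  `docs/methods.md` on BIC's liberality and the tie-breaking effect of
  delay residualization).
* `network_comparison.p_value: 0.1798` — on this single cohort draw the
  permutation test (1000 regroupings) does not reach significance; across
  repeated cohorts at this size the test detects the sparse-vs-dense
  contrast in most but not all draws, which is the expected power at
  n ≈ 150 per occasion.
* `centrality_stability.stability.endpoint.cs_coefficient: 0.2` — node
  strength is not stable enough to interpret here (CS < 0.25), common at
  clinical sample sizes.

The same steps are available piecemeal (`honosnet scores`, `network`,
`compare`, `centrality`, `stability`) and as library calls
(`honosnet.run_full_analysis`, `honosnet.estimate_network`, ...).

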
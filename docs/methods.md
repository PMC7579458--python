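# Methods

`rxanomaly` implements a two-stage screen for abusive or fraudulent
outpatient insurance claims: (1) a multi-label neural network learns which
drugs plausibly accompany which diseases and condenses each claim's
disease–prescription fit into a single *relation score*; (2) that score
joins a set of engineered fee/frequency/person features, and unsupervised
outlier detectors rank claims for analyst review. Because real claims data
of this kind is private, the package ships a calibrated synthetic
generator that plays the role of the study population; everything below is
exercised on it.

## The synthetic claims world

`synthetic.GeneratorConfig` defines the study conditions. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_records` | 10,000 | claims per draw |
| `n_diseases`, `n_drugs` | 1000, 1000 | catalogue sizes (modelling universe) |
| `zipf_ratio` | 120 | frequency of the top disease over the rank-1000 disease |
| `mean_amount` | 300 | mean fee of a normal visit (currency units) |
| `abnormal_amount_multiplier` | 5 | abnormal mean fee over normal mean fee |
| `anomaly_rate` | 0.10 | abnormal share of records (exact, not stochastic) |
| `comorbidity_rate` | 0.25 | probability a visit carries secondary diseases |
| `drugs_per_disease` | 10 | size of each disease's compatible drug pool |

Disease frequencies follow a power law `freq(r) ∝ r^(-s)` with the
exponent solved in closed form from the endpoint condition
`freq(1)/freq(n) = zipf_ratio`, so the head-to-tail skew is met exactly.
Every disease owns a fixed pool of compatible drugs (drawn once per seed
with a popularity skew, so common drugs serve many diseases); normal
visits prescribe only from the pools of the diseases on the claim. Unit
prices are log-normal per drug and scaled so a normal visit averages
`mean_amount`. Persons carry 1–20 visits each so that visit-history
features are non-degenerate.

Exactly `round(n_records × anomaly_rate)` records are abnormal, the quota
split across six abuse patterns by largest remainder of `pattern_mix`:

1. **dosage abuse** — the priciest compatible drug's quantity inflated ≥ 5×;
2. **duplicate test** — one test billed ≥ 3 times in a single visit;
3. **unrelated drugs** — the drug lines *replaced* by off-indication drugs
   (biased toward the top price decile). Replacement rather than addition
   matters: the relation score is a ratio of predicted mass on prescribed
   drugs to total predicted mass, so merely *adding* an unrelated drug
   leaves it nearly unchanged — only a prescription dominated by
   off-indication drugs scores low, which is also the realistic reading of
   this abuse pattern;
4. **unrelated service** — a service incompatible with the primary disease;
5. **similar-effects abuse** — 2–4 extra drugs from the same compatible
   pool at full dosage each;
6. **excessive frequency** — a dedicated person with ~2 visits/day over a
   few days, each visit collecting inflated drug quantities; one burst
   spends several records of the abnormal quota.

Abnormal fees are sized toward per-record targets drawn from a Gamma
distribution. Pattern 3 targets ~1.5× a normal visit (an off-indication
prescription is not intrinsically expensive); the other five patterns
carry proportionally larger targets so that the *collective* abnormal mean
sits at `abnormal_amount_multiplier` × the empirical normal mean. Abuse is
also skewed toward pharmacies and private hospitals in the provider mix.

What the generator does **not** emulate: real coding systems (codes are
synthetic tokens), geography, seasonal effects, provider-level collusion,
combined patterns on one claim (patterns are mutually exclusive per
record), or label noise — real analyst labels disagree; synthetic labels
are exact. Passing tests therefore demonstrate that the pipeline recovers
structure *of this kind*, not field performance on any real claims system.

## Relation model

Claims are clipped to the top-`K` diseases and drugs by corpus frequency
(ties broken lexicographically); claims touching out-of-vocabulary codes
are excluded as uncovered. Before training, the disease long tail is
flattened by the adjustment factor: a disease with `c` samples is
resampled to `round(min(target_mean/c, 10)·c)` samples (downsampling
without replacement, upsampling with), the 10× cap preventing rare-disease
overfit. Grouping uses the sample's lowest disease index — for
single-disease claims exactly the primary disease.

The network maps the multi-hot disease vector through a dense layer to 512
units, reshapes to a 2×16×16 grid, applies two 3×3 convolutions — stride 1
to 16×16×8, then stride 4 to 4×4×32 (this stride pairing realises the two
stated channel shapes; kernel sizes and strides are otherwise free
choices) — and decodes through a 256-unit dense layer to one sigmoid logit
per drug. An optional gated refinement recurrence (default 2 steps)
re-feeds the squashed logits through a shared dense candidate and an
element-wise gate, letting co-prescription structure adjust the output;
disabling it (`refine_steps=0`) changes nothing but the capacity.
Training is plain mini-batch Adam (lr 1e-3 module default, batch 256) on a
hand-written numpy engine with analytically derived gradients, verified
against numerical differentiation in the test suite.

Two objectives are implemented, summed over drug labels:

* multi-label binary cross-entropy
  `−Σ_k [y_k log p_k + (1−y_k) log(1−p_k)]`;
* focal loss `−Σ_k α_t (1−p_t)^γ log p_t` with `p_t = p_k` for positive
  labels and `1−p_k` otherwise, defaults γ = 2, α = 0.25. At γ = 0,
  α = 0.5 it is exactly half the cross-entropy.

The focal focusing term suppresses gradients of easy negatives, which at
small step budgets freezes the background probability near wherever it
starts; the output bias is therefore prior-initialised so every label
begins near a typical positive rate. Even so, on a single CPU and a few
epochs the focal objective leaves the predicted mass diffuse, while the
cross-entropy objective reaches the concentrated regime in which the mean
per-drug probability (~0.002) sits two orders of magnitude below the mean
relation score (~0.35). The module default follows the focal objective;
the benchmark pipeline (`pipeline.RunConfig`) trains with cross-entropy
for 8 epochs at lr 3e-3 for this reason.

The **relation score** of a claim is

    p = Σ_k y_k · y_gt_k / Σ_k y_k ,

the share of the model's total predicted drug-probability mass that falls
on the drugs actually prescribed — in [0, 1], invariant to rescaling the
prediction vector, and 0 by definition for an all-zero prediction.
Prediction ranking quality is summarised by *one-error* (share of claims
whose top-ranked drug is not prescribed) and *coverage* (mean 1-based rank
of the worst-ranked prescribed drug, minus one); both break score ties
toward the lower drug index.

## Features, selection, normalization

Each covered claim becomes ~24 named features in four blocks (trailing
365-day fee aggregates with the current claim excluded from its own
history; visit counts, mean inter-visit gap — single-visit persons get the
global maximum gap as a flagged sentinel — and distinct providers;
person attributes including two synthesized proxies, a fund-balance and a
credit-score stand-in, deterministic functions of identity/history since
no administrative formula exists here; and treatment features led by the
relation score, plus the complementary insurance/self pay rates).
The 20 features most informative about a 1000-record labelled slice are
kept, ranked by a plug-in mutual-information estimator on 10
equal-frequency bins (deterministic, oracle-checkable against raw
contingency tables — preferred over k-NN MI estimators for exactly that
reason). Selected features are min-max normalised to [0, 1] with bounds
fitted on the corpus and clipped at apply time; constant columns map to 0.

## Outlier detectors and evaluation

Five scorers rank the normalized features (higher = more anomalous):
isolation forest (100 trees, 256-point subsample — reduced with a warning
when fewer rows exist), k-means distance to the nearest of k = 8
centroids, DBSCAN noise flag (noise ties ordered by distance to the
nearest core point), local outlier factor (20 neighbours), and the
pre-ML baseline: a weighted sum of per-column percentile ranks (equal
weights when none are given). Ranking ties always fall back to
`claim_id`, making every ranking reproducible. A hand-rolled SMOTE
(k = 5 same-class neighbours, singleton classes replicated with jitter)
supports the 10× augmentation experiment.

The triage metric is the **detection rate** DR@f: the abnormal share of
the top `⌈f·N⌉` ranked claims (default f = 0.10). With prevalence equal to
f, this coincides with recall of the top window; the window-size
denominator is the deliberate choice and is what `detection_rate`
computes. `audit_windows` counts labelled abnormals inside fixed-size
windows at chosen ranking depths, and `compare_detectors` reports mean ±
sd DR over reseeded runs, optionally on the SMOTE-augmented copy.

## Pipeline, seeds, and problem sizes

`run_pipeline` chains generate → clean → encode → resample → train → score
→ featurize → select → normalize → detect → evaluate, writing every
intermediate artifact plus a manifest (config hash, per-stage seeds,
counts, timings). All stage seeds derive from one root seed by hashing
`(seed, stage_name)`, so a single integer reproduces a run; fixed-seed
stages reproduce byte-identically.

The shipped benchmark runs at 10,000 claims per draw with the generator
defaults above — large enough that per-disease sample counts span three
orders of magnitude and detector DR estimates are stable to a few points,
while a full run (including network training) stays around a minute on one
CPU. The heavier checks train on a 20,000-record, 50-disease toy world.

## Known limitations

* The refinement recurrence is a gated approximation of an output-rethink
  architecture, not a reproduction of any specific published wiring.
* Mapping 512 hidden units onto a 2×16×16 grid is a declared convention;
  nothing in the problem fixes the grid shape.
* The MI selector ignores feature redundancy (it is a filter, not a
  wrapper); correlated fee aggregates are routinely co-selected.
* DBSCAN yields a binary score, so its DR depends almost entirely on how
  many points fall out as noise at the chosen `eps`.
* Synthetic anomaly prevalence (10%) is far above field rates; detectors
  tuned here may need recalibrated contamination assumptions elsewhere.
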
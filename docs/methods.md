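# Methods

This note documents the models and procedures `pidiag` implements, the
parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions, so results can be
interpreted and the design decisions audited.

## The experimental design being modelled

The pipeline targets a two-colour (Cy3/Cy5) oligonucleotide-array
experiment tracking leaf gene expression around a phosphate
withdrawal/re-supply cycle: sampling days (0, 1, 3, 7, 17, 29, 31)
relative to withdrawal, with Pi re-supplied after 28 d, two treatments
(full nutrient solution vs no Pi), and three biological replicates per
cell. Each treated/control pair of the same day and replicate is
co-hybridised on one array, and a full dye swap repeats every pairing
with dyes reversed: 42 biological samples, 42 arrays, 84 labelled
sample-channels. (The pairing of samples to arrays is the simplest one
consistent with a full dye swap; published designs often leave it
implicit.) The companion "field" set is one-colour: 15 fertilised and
15 unfertilised samples.

## Synthetic data

`generate_timecourse` plants multiplicative treatment effects on a
log-normal signal model: log2 baselines are uniform on [7, 13] (bright)
or [3, 5] (a `frac_low_signal` subset, kept disjoint from the
responsive genes so filter behaviour and detection power can be
measured separately), and each channel value is
2^(baseline + effect + ε) with ε ~ N(0, noise_sd²), the standard
microarray error model (keeps signals positive; default noise_sd 0.2 on
log2, ≈15% CV). A responsive gene (fraction `frac_responsive`, default
0.1) carries a seven-symbol pattern over {↑, ↓, −}; at days marked ↑
the treated mean is multiplied by `effect_fold` (default 2), at ↓
divided, at − untouched.

Two pattern pools are used:

- **Windowed patterns** (default): six two-arrow patterns — early
  (days 3–7), mid (7–17) and late (17–29) windows, induction and
  repression in equal measure. These mirror the empirically observed
  response clusters (responses split roughly evenly between up- and
  down-regulation) and each crosses the 1.5-fold threshold at two days,
  so planted genes are callable under the ≥2-time-point rule.
  One-arrow patterns exist in real data but are deliberately not
  planted by default: they cannot satisfy the calling rule, so they
  would make "sensitivity on planted genes" measure the calling rule's
  definition rather than the pipeline's power.
- **Status-tracking patterns** (`STATUS_PATTERNS`): ↑ (or ↓) at every
  deficiency day. This is the idealisation of a diagnostic marker —
  expression follows Pi status itself — and is what the marker-recovery
  benchmark plants, because there "a planted fold-2 diagnostic gene"
  must mean a gene with a genuine fold-2 separation between the
  deficient and replete classes. Windowed genes respond in only ~40% of
  deficient channels and are effectively fold-1.3 class markers.

Absent flags are i.i.d. per gene × channel cell (default rate 0.02) —
the simplest model that exercises the absent-flag filter. Dye bias is
injected as a smooth polynomial of centred mean log-intensity added to
the log-ratio, split symmetrically between channels so the intensity
coordinate is untouched and the distortion is exactly what Lowess
normalization is built to remove.

`generate_field_set` shifts every diagnostic gene of the deficient
class by `attenuation × log2(planted_fold)` in the gene's response
direction (default attenuation 0.8 — field responses are damped
relative to hydroponic withdrawal — and noise_sd 0.25, reflecting the
extra biological variability of field material). Baselines are drawn
afresh: a field dataset is a different hybridisation batch, and the
classifier never sees raw baselines (see feature convention below).

What the generator does **not** emulate: probe-sequence effects,
spatial array artefacts, scanner saturation, correlated absent flags,
batch-specific intensity distributions, and the long tail of weak or
partial responders present in real transcriptomes. Passing tests
therefore demonstrate the pipeline's correctness and its behaviour
under the stated statistical structure, not performance guarantees on
real arrays.

## Preprocessing

Per array, M = log2(experimental / max(control, 10)) is regressed on
A = (log2 E + log2 C)/2 by Lowess — local linear fits, tricube weights,
35% of the data per fit, two robustness iterations (via statsmodels,
with an interpolation delta of 0.5% of the A-range for speed) — and the
fitted trend is subtracted. The control floor of 10 caps ratios of
near-background spots. On a bias-free noiseless fixture the operation
is idempotent to numerical precision; with noise, re-application moves
log-ratios only at the smoother's own scale.

Median scaling divides each gene by the median of its measurements
across all samples of a dataset; genes with a non-positive median are
reported and dropped.

The three pre-filters are evaluated on per-time-point aggregates
(replicates and dye orientations pooled by mean within each day),
since per-channel evaluation would make rule 1 fire on single noisy
channels: (1) mean raw signal < 50 at ≥5 of the 7 time points; (2)
absent-flagged in >50% of measurements (the count threshold is a
package choice; flag-based filters rarely publish one); (3) per-day
mean normalized ratio inside the closed band [0.8, 1.2] at all time
points. A gene may fire several rules; the removal report records all
of them.

## Differential expression

The treatment-response test is an extra-sum-of-squares F comparing the
full treatment × day cell-means model against the day-only model on
log2 signals (numerator df = cells − days = 7; denominator
df = n − cells = 70 for the default design). Testing main effect and
interaction jointly is deliberate: a gene responding only late in the
time course has little main effect but a strong interaction. The
implementation is vectorised over genes and agrees with a per-gene
nested-model ANOVA from statsmodels to 6 significant figures.
Degenerate genes (residual variance at rounding level) get p = 1 (no
evidence) or p = 0 (perfect separation); a dataset whose genes are all
degenerate raises an error.

Raw p-values get the Benjamini–Hochberg step-up adjustment. Calling:
up ⇔ adjusted p < α (default 0.01) and fold > 1.5 at ≥2 of 7 days;
down with fold < 1/1.5; a gene may carry both calls (different days)
but is one member of the DE set.

DE profiles (log2 fold changes per day) are clustered by average
linkage on centred correlation distance — the classic
expression-clustering defaults — and the tree is cut to exactly
`n_groups` (default 8) clusters; flat profiles are defined to have
correlation 1 with each other (duplicates must co-cluster) and 0 with
everything else. Group labels are numbered by first appearance in the
gene list so the labelling is deterministic. Symbolization maps a
per-day fold to ↑ (>1.5), ↓ (<1/1.5) or −.

Term enrichment is the one-sided upper-tail hypergeometric test
against the post-filter gene universe (the analysed set, not the whole
array), BH-adjusted across terms. The Welch t-test accepts published
summary statistics (mean, SEM, n per group) and uses the
Welch–Satterthwaite degrees of freedom; whether a published table used
Welch or pooled variance is often unrecoverable, which is why the
field-trial check carries a ±0.01 tolerance on the p-value.

## Class prediction

Feature convention: log2 of per-gene median-scaled signals, scaling
done **within each dataset** (the 84 training channels together; a
field set within itself). Cross-dataset comparability is the weakest
link of any transfer of array classifiers and no convention fully
solves it; within-dataset median scaling is the declared, documented
choice, and its consequence — a balanced test set sits symmetric about
zero while the training classes do not — drives two kernel choices
below.

Golub score: s(g) = (μ_def − μ_rep)/(σ_def + σ_rep) with sample
standard deviations and a denominator floor of 1e-9 × the mean pooled
sd. Selection is balanced by default — ⌈k/2⌉ most positive, ⌊k/2⌋ most
negative, ties broken by gene id — with pure |s| ranking as an option.

Kernels: polynomial dot product (scale·u·v + 1)^d for d ∈ {1, 2, 3}
and RBF exp(−γ‖u−v‖²), with scale and γ defaulting to
1/(n_features × var(X)) at training time (the standard heuristic; it
also makes linear-kernel margins exactly invariant to a global feature
rescaling, which is tested). The polynomial offset of 1 is essential,
not cosmetic: with median-centred test data the two field classes sit
near +x and −x, and an even-degree *homogeneous* kernel satisfies
k(u, −x) = k(u, x) — it cannot separate them even in principle. The
homogeneous variant remains available (`KernelSpec(offset=0)`).

The soft-margin dual (C default 1.0, KKT tolerance 1e-4) is solved by
libsvm via scikit-learn; the returned model stores support vectors,
dual coefficients αᵢyᵢ and bias, and all predictions are computed from
those with the package's own kernel functions, so a serialised model is
solver-independent. Tests check the dual constraints, the ±1 margins of
free support vectors on separable data, and agreement within 1e-2 with
an independent SLSQP solution of the same QP on small instances.

Class coding is deficient = +1 throughout: a positive margin means
"this sample looks Pi deficient". The evaluation grid selects on the
training set, fits each kernel, predicts the test set and tabulates the
four confusion counts and percent correct (one decimal).

## Ortholog transfer

A mapping table of (source, target) records projects a diagnostic set
onto a second platform: one-to-many sources resolve to their first
record (file order), many-to-one targets collapse by the arithmetic
mean of log2 signals. What labelled target-platform data to train on is
an explicit input — the module does not guess it. The permutation
negative control routes the whole transfer (reference projection and
feature selection) through a shuffled map while the test data keep the
true orthology, which is the situation a wrong map creates in practice;
it reduces accuracy to chance.

## Benchmark problem sizes

The validation battery runs at: DE recovery 500 planted among 5,000
genes (noise 0.2); null FDR 1,000 replicates × 1,000 genes; dye-bias
removal 10,000 genes; marker recovery 200 planted among 20,000 (noise
0.25, status-tracking patterns); field grid 20,000 genes with the
default 10% responsive pool (the diagnostic set is selected from a
larger responsive pool, as in any real marker study) and a 15+15 field
set at attenuation 0.8; transfer 4,000 genes. These sizes give each
check clear statistical resolution while keeping the full battery in
the tens of seconds on one CPU.

## Known limitations

- Cross-dataset feature comparability (above) is assumed, not solved;
  margins are comparable within a dataset, less so across platforms.
- The ANOVA assumes homoscedastic Gaussian noise on the log2 scale;
  variance-intensity trends present in real arrays are not modelled
  (nor shrunk, as moderated-statistic methods would).
- The tree cut to exactly k groups can return fewer when merge heights
  tie; group *identities* are arbitrary (only memberships matter).
- Margins are uncalibrated distances, not probabilities; no
  cross-validation or model selection beyond the published-style
  kernel × size sweep is provided.
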
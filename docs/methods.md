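# Methods

This note records the models implemented in `cgrm`, the numerical and
design choices behind them, what the synthetic benchmark does and does not
emulate, and known limitations.

## Kinetic TF-logic model

Transcription of a target gene is modelled as
`I_s(t) = I_max(1 − exp(−k_b·Y(t−T_m)/I_max))`, the closed form of the
alternating series `I_max·Σ_{n≥1}(−1)^{n+1}(k_b/I_max)^n Y^n/n!`. The
closed form is the production path; the partial sum exists only as an
independent cross-check. Note the truncation error of an N-term partial
sum is the first omitted term, `u^{N+1}/(N+1)!` with `u = k_b·Y/I_max`:
at N = 30 the two agree to machine precision for u ≲ 5 but only to ~1e-3
at u = 10, so cross-checks at large activation must raise N (60 terms
cover u ≤ 10 to < 1e-12).

**Occupancy algebra.** Per-TF occupancy is the static binding strength
(per-TF min–max normalized onto (0, 1] at load, with a 0.05 floor so the
weakest observed pair remains distinct from absence) optionally modulated
by a TF activity trajectory; by default activity is proxied from the TF's
own expression row, min–max scaled. Logic combination is `y1·y2` (AND),
`y1+y2−y1·y2` (OR), `y1(1−y2)` (NOT); it matches the Boolean truth tables
at {0, 1} and interpolates continuously. The ">" operator is implemented
as repression, not temporal precedence.

**Fitting.** The observed rate proxy is the first-order finite difference
`r_k = (E_k − E_{k−1})/Δt (+ λE_k` with optional decay `λ`, default 0`)`,
matched against the model rate at the lagged occupancy index `k − T_m`
(`T_m` is an integer index shift, default 1). Parameters `(I_max, k_b)`
are estimated by bounded least squares (trust-region reflective, analytic
Jacobian, three `k_b` starts at {0.1, 1, 10}× the rate scale,
deterministic). Two numerical guards matter:

* *Whitening.* Under multiplicative measurement noise the proxy's errors
  have variance ∝ `E_k² + E_{k−1}²` and covariance `−E_k²` between
  neighbours (the shared term). Residuals are whitened with the Cholesky
  factor of this tridiagonal covariance, estimated from the observed
  series. This is the main determinant of noisy-data performance: in the
  recovery benchmark at 5% noise, ordinary least squares ranks the
  planted logic first for ~60% of genes, the whitened fit for ~84%.
  `whiten=False` restores plain least squares.
* *Identifiability cap.* When the fit never saturates only the product
  `k_b·Y` is identified and `I_max` drifts upward on a flat likelihood;
  it is capped at 1000× the observed rate scale. With constant occupancy
  the pair `(I_max, k_b)` is never separately identifiable — parameter
  recovery claims require time-varying occupancy.

**Confidence.** Candidate logics for a gene (all singles, unordered
AND/OR pairs and ordered NOT pairs over its bound TFs; ≤ 2 TFs per logic)
are scored by normalized AICc weights computed from RSS/n with parameter
count 2 (plain AIC when n ≤ 3, where the small-sample correction
degenerates; an RSS floor of n·1e-24 guards exact fits). Per-gene
confidences sum to 1; a gene is reported when a logic reaches the 0.9
default threshold. This scoring preserves the intended semantics of the
threshold — a single dominant logic — without claiming equivalence to any
particular matching-probability formulation.

## Differential expression

Welch's t on log2(x+1) between two disjoint groups of time points, fold
change `log2(mean_b/mean_a)` on the linear scale with pseudocount 1.
Cutoffs: |FC| ≥ 2 and p < 0.05 (raw by default; BH behind a flag).
Singleton groups get p = 1 with a warning. This deliberately simple test
stands in for count-based DE engines; externally computed tables are
accepted via `read_deg_table`.

## Regulator activity factorization

The primitive `solve_interaction_strengths` solves, per gene, the
non-negative least squares `min_{y≥0} ‖x − y·Z‖²` (Lawson–Hanson;
closed form for a single activity row). The production route
`rca_analysis` wraps it with two model-motivated choices, both
switchable:

* **log scale** — regulation acts multiplicatively, so X and Z are taken
  as log2(x+1); a planted fold-effect is then exactly additive, matching
  the linear factorization.
* **augmented design** — all genes share a developmental trend and a
  gene-specific baseline level; the activity matrix is augmented with a
  background row (median profile over the analysed genes) and a constant
  row. Their coefficients absorb trend and level, so regulator
  coefficients measure regulator-specific modulation. Without this,
  strengths track expression magnitude and ranking degrades sharply.

**Permutation test.** Each of `n_perm` (default 1000) permutations
shuffles every gene row's sample labels independently (preserving each
gene's value distribution, breaking temporal alignment with Z) and
re-solves; `p = (1+#{perm ≥ obs})/(n_perm+1)`, never exactly 0.
Permutation streams are Philox-keyed by (seed, permutation index), so
results are independent of execution order. The alternative null —
shuffling target memberships when building Z — is available via
rebuilding maps, but within-gene shuffling is the default.

Two calibration caveats are intrinsic and documented rather than patched:
(1) with several regulators solved jointly, NNLS produces exact zeros;
tied zero strengths make their permutation p-values conservative (an atom
at p = 1), so uniformity holds only where the statistic is continuous —
the calibration experiment therefore uses single-regulator analyses;
(2) genes that build a regulator's Z row are positively biased for that
regulator (flagged `circular_flag` in all outputs) and must be excluded
from calibration, which uses a held-out target block. Both effects were
confirmed empirically (KS rejects uniformity when either is violated).
Up- and down-regulated DEG groups are analysed separately; a direction
with < 2 genes is skipped with a warning.

## Association statistics

Jaccard `|A∩B|/|A∪B|` (0 for two empty sets), Simpson
`|A∩B|/min(|A|,|B|)` (undefined for two empty sets), hypergeometric
over-representation `P(X ≥ k)` via the survival function in log space,
and CSI: the fraction of third parties whose similarity to both members
of a pair falls below `sim(a,b) − gap` (gap 0.05), on a Jaccard
similarity substrate by default. Enrichment tables carry BH q-values per
target-set family, reported alongside raw p (never replacing it). The
default universe is the expression matrix's gene set.

## Network assembly and conservation

Edges require evidence: a logic fit (confidence ≥ threshold, strict ≥)
or an interaction with p < α (strict <). Pairwise logics are first-class
nodes (e.g. `"TF2 | TF3"`) with membership edges to their TFs, so a
co-acting pair is a unit in the graph; single-TF logics use the TF node
directly. A regulator that is itself differentially expressed appears as
one node with its regulator kind and DEG direction. Conservation is
reference-anchored: a (gene, regulator) pair is conserved iff present in
the designated reference dataset and ≥ `min_other` (default 1) other
datasets; a gene is conserved if any of its pairs is. Exports: TSV
(nodes + edges, lossless), JSON (lossless), GraphML (attribute-carrying).

## Synthetic benchmark

The generator emulates the *shape* of time-course differentiation data:
10–14 ordered time points, a few master TFs with smooth staggered
sigmoid activity waves (midpoints stratified across the first two-thirds
of the series, balanced rising/falling, gentle slopes), genes integrated
forward on the observation grid from the kinetic model (so the
finite-difference proxy is exact at zero noise), coherent per-regulator
ncRNA fold-modulations (folds log-uniform in [1.5, 4], up/down split
across regulators, rising or pulse activity waves), and multiplicative
log-normal noise at a configured CV. Default kinetic conditions: `I_max`
log-uniform [1, 10] expression/time-step, `k_b` log-uniform [0.5, 2],
initial expression uniform [0.02, 0.1] (induced genes start near off),
operand binding strengths uniform [0.5, 0.8]. The regulator-recovery
variant (`make_ncrna_truth`) instead uses weak transcriptional drive
(`I_max` ∈ [0.1, 0.5]) on an expressed baseline (`E0` ∈ [2, 6]) over 14
time points, isolating the post-transcriptional signal that stage is
meant to recover. Memberships default to disjoint target blocks (~70% of
genes partitioned); an overlapping mode exists but compound multi-regulator
effects on one gene make attribution intrinsically ambiguous.

Three generator choices are identifiability-driven and worth knowing
when interpreting benchmark results on real data:

* regulators act coherently on their targets — a regulator whose targets
  split up/down cancels out of its own median activity profile;
* ncRNA activities are rising waves or pulses only — a falling activity
  with positive effect equals a rising activity with negative effect up
  to a constant, a degeneracy no level-free factorization resolves;
* TF activity waves are mutually distinct — two TFs switching at the
  same time in the same direction are not distinguishable operands.

Real data need not satisfy any of these, so passing benchmarks certify
the inference machinery (correct solver, calibrated p-values, recovery
when structure is identifiable), not performance on arbitrary datasets.
The generator also does not emulate count sparsity, batch effects,
library-size artefacts or single-cell dropout.

Reference evaluation conditions (`cgrm.benchmarks`): logic recovery on
100 genes × 4 TFs × 11 time points, noiseless and at CV 0.05 (the noisy
rate is pooled over six replicate datasets, 600 genes); regulator
recovery on 300 genes × 6 ncRNAs × 14 time points at 1000 permutations;
calibration on five independent single-regulator null analyses per seed
(500 pairs). These sizes keep the full evaluation within a few minutes
on one CPU while leaving the recovery rates stable to a few percent
across seeds.

## Pipeline

`cgrm run` executes deg → logictrn → rca → associate → grn from one YAML
config whose defaults are the published operating point (FC ≥ 2.0,
p < 0.05, confidence ≥ 0.9, T_m = 1, 1000 permutations, α = 0.05, CSI
gap 0.05). Stage outputs are plain TSVs; `manifest.json` records version,
seed, stage order and SHA-256 checksums; reruns with identical config and
seed are byte-identical. A stage failure keeps prior outputs and leaves a
`<stage>.partial` marker naming the failed stage.

## Known limitations

* Logics are limited to two TFs; higher-order combinatorics are out of
  scope.
* The kinetic model has no degradation network; the optional linear decay
  term is a per-gene scalar.
* The factorization is unregularized; heavily collinear activity
  profiles split strength arbitrarily among near-equivalent regulators.
* Permutation p-values for jointly-solved multi-regulator analyses are
  conservative at the zero boundary (see above); treat `p = 1` entries
  with `strength = 0` as "no evidence", not calibrated nulls.
* Gene identifiers are opaque strings; no symbol mapping, GEO parsing or
  count normalization is performed.
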
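# Methods

## The measurement and the inference problem

A high-density peptide microarray presents every overlapping 16-mer of
a proteome (step 2 aa for reviewed proteins, 4 aa for most unreviewed
ones; identical peptides synthesized once and mapped back to all of
their protein positions).  Incubating a serum on a chip yields one
relative-fluorescence value per unique peptide, driven by the titer and
avidity of antibodies recognizing that peptide.  Given chips for naive
and immune sera from the same mice, the task is to decide, per immune
serum, which probes are antibody-bound; to merge bound probes into
epitope regions with a consensus sequence; to roll regions up to
proteins; and to count co-recognition across mice (K of N).

## Probe library

Tiling starts at 1, 1+s, 1+2s, … while a full 16-mer fits.  When the
last regular probe does not end at the C-terminus, one extra probe
anchored at `L−15` is appended so the terminal residues are covered
(disable with `cterm_anchor=False` for strict arithmetic tiling).
Proteins shorter than 16 aa are skipped with a warning; probes
containing nonstandard residues (X, U, B, Z) are kept but flagged, and
the simulator never spikes them.  The unique peptide is the probe key;
occurrences are `accession:start` with 1-based inclusive coordinates,
and a probe covers `[start, start+15]`.  Measured values are processed
once per unique peptide and restored verbatim to every occurrence
before any protein-coordinate operation.

## Preprocessing

Order fixed: log2 → quantile normalization (all samples jointly; ties
receive the mean of the rank means they span) → restoration to
occurrences → sliding mean over probe *start* positions within ±8 aa,
truncated at protein ends and never crossing protein boundaries.  For
fixed-length probes a midpoint anchor would give identical window
membership (midpoints are starts shifted by a constant), so no anchor
option is exposed.  Nonpositive raw values are an error unless a
pseudocount is supplied.  The pre-smoothing normalized matrix is kept
alongside the smoothed one: smoothing is the right input for positional
calling, but chip-versus-chip probe reproducibility is a property of
the per-chip values, so replicate scatter uses the normalized matrix.

## Hierarchical calling

Antibody binding only elevates signal, so all tests are upper-tail.

- **Global test**: z of the smoothed value against the mean and SD of
  the entire processed matrix (all probes × all samples).
- **Differential test**: one-observation-versus-group t against the
  naive sera at the same occurrence, `t = (x − x̄)/(s·√(1+1/n))`,
  df = n−1, with a variance floor (default 0.01 log2 units) guarding
  degenerate naive SDs.  With n = 5 naive sera the t₃/t₄ tails are
  heavy; a probe 100 floor-units above constant naive still has
  p ≈ 1.5e−6, not arbitrarily small.
- **Combination**: Wilkinson's maximum with k = 2, `p = max(p_g, p_d)²`
  — the exact null CDF of the larger of two independent uniforms.
  Demanding both tests simultaneously is what suppresses naive
  autoantibody background (high signal, no differential) and stray
  differential noise (low signal).
- **FDR**: Benjamini–Hochberg within each immune sample at each level
  (probe, epitope, protein); called iff q ≤ 0.05.
- **Singleton removal**: a called probe with no called probe within one
  tiling step on either side (same protein, same serum) is dropped
  unless the same probe is called in a replicate chip of that serum.
  Real chips show sparse single-probe artifacts; genuine epitopes light
  several overlapping probes.
- **Tiers**: inclusive/moderate/restrictive at >3/>6/>10 SD above the
  pooled mean (strict inequalities, ≤ for the FDR cutoff).  An epitope
  or protein is in tier T iff it is FDR-called and its strongest member
  smoothed signal clears the tier-T cutoff.

### Epitope segmentation

Called occurrences adjacent on the probe grid (gap ≤ the tiling step by
default) form chains.  A chain's contiguity graph is a path, whose
minimum spanning tree is the path itself, so SKATER-style tree-edge
removal reduces to recursive best-single-cut splitting that minimizes
within-cluster sum of squared deviations of the feature vectors
(per-sample −log10 combined p).  Stopping rule: a cut is accepted while
its SSD decrease exceeds a noise-scaled penalty, `0.2 × σ̂² × log n`,
with σ̂² the per-column noise variance estimated robustly from
successive differences along the chain (median of squared differences,
corrected for the χ²₁ median and the factor 2 of differencing).
Smoothing turns an epitope into a gentle hill of signal, and a
threshold tied to the whole chain's SSD systematically under-splits
such hills, merging plateau and shoulders; the noise-scaled penalty
accepts exactly the cuts that local jitter cannot explain.  A
chain-SSD-fraction rule is still available via `min_gain_frac`.

### Consensus and intervals

For k members on a step-s grid the shared stretch is
`[max start, min start + 15]`, length `16 − s(k−1)` — five consecutive
2-aa-tiled 16-mers share 8 aa.  Regions longer than one probe of
overlap have no common core and report their full span flagged
`no_common_core`.  A region's best epitope-interval estimate (used for
truth matching and replicate matching, Jaccard ≥ 0.5) is the core when
it exists, else the span.

### Meta p-values and K of N

Epitope p per sample: the Beta(n−1, 2) CDF evaluated at the
second-largest member combined p (the (n−1)-th order statistic of n
uniforms), so one outlier probe cannot carry a region; singleton
regions keep their member p.  Protein p: Tippett's minimum,
`1 − (1 − p_min)^m` over the protein's epitopes.  Both are exactly
uniform under independent uniform nulls (property-tested by KS).
K of N counts recognizing mice, with replicate chips of one serum
collapsed to their mouse; N is the number of distinct immune mice.

## Synthetic experiments

The generator emulates the study design at a size that runs in seconds:
200 proteins (gamma lengths, mean 120 aa, i.i.d. residues at natural
frequencies) ≈ 10–12k probes; 6 immune mice of which 5 contribute
matched naive sera; the first two immune sera assayed on replicate
chip pairs (batch 2, with a 0.2 log2 batch shift).

Signal model, per probe and chip, on the raw scale:

```
raw = min( 2^(μ + a_i + serum + shift + η),  ceiling ) + 2^(μ + ζ)
```

- baseline μ = 6 log2 (≈64 counts); probe affinity `a_i` ~ N(0, 0.3);
- `serum`: the mouse-and-condition binding signal — spiked epitopes in
  immune sera, naive-background probes in both conditions of a mouse;
- `shift` = log2(1.5) for immune chips (hyper-immune sera carry
  multi-fold immunoglobulin);
- two-component noise: a lognormal optical floor (ζ, SD 0.4 log2)
  dominating near baseline plus a small multiplicative chip noise
  (η, SD 0.08 log2), so log-scale scatter tightens as signal rises —
  the classic fluorescence error structure;
- sparse bright single-probe artifacts (0.5% of probes per chip,
  +1–3 log2): the error-prone single-peptide values that motivate
  singleton removal and the epitope level;
- a 16-bit scanner ceiling (2¹⁶ counts ≈ 1000 × baseline), where the
  strongest binders saturate.

Epitopes are placed disjointly (≥32 aa apart within a protein), lengths
uniform 8–12 aa.  A probe binds with weight 1 when its window contains
the whole epitope and with steeply reduced avidity
(`((overlap − L/2)/(L − L/2))³`) when it carries at least half of it;
probes with less than half do not bind.  Amplitudes are truncated-
Pareto draws (exponent 1.2) in background-SD units (1 SD = 0.5 log2):

- **strong truth epitopes** (10 private per immune mouse, 8 shared with
  K drawn uniformly from 2..6): 13.2–20 SD, i.e. 100–1000-fold raw —
  the strong-binder range; these are the recovery targets;
- **weak reactivities** (25 per mouse, flagged `weak` in the manifest):
  3–8 SD, the low end of the serum binding continuum; they populate the
  inclusive/moderate boundary and are not recovery targets;
- **naive background**: 0.1% of probes per mouse elevated 8 SD in both
  conditions (autoantibody binding that the differential test must
  ignore).  The rate is a free parameter, not an empirical value.

All draws come from named substreams of one seed
(`SeedSequence(seed, spawn_key=(stage,))`), so identical configs give
byte-identical outputs.  The matched ELISA panel maps the underlying
titer through a saturating logistic to optical densities clipped to
[0, 3.5], with replicate wells.

What the generator does *not* model: spatial chip structure and its
correction (inputs are taken as spatially corrected), probe synthesis
quality, sequence-composition affinity biases, conformational or
modified epitopes, and cross-reactivity between distinct sequences.
Passing the recovery and calibration tests therefore demonstrates the
statistical machinery on data with the assumed structure, not
performance on any real serum.

## Replicate concordance

Directional: the fraction of items called in chip B also called in chip
A, and the converse, per level and tier.  Probe membership ("sd" mode)
thresholds the pre-smoothing normalized values, matching how per-chip
probe reproducibility is measured; "sd+fdr" additionally requires the
FDR call.  Epitopes match by interval Jaccard ≥ 0.5, proteins by
accession.  Expected pattern: concordance rises from inclusive to
moderate to restrictive and from probe to epitope to protein — the
pattern is statistical, and with call sets of tens of items a single
boundary-hugging region moves several percentage points, so the test
suite asserts the absence of a statistically significant decrease
(one-sided two-proportion test, α = 0.01) on counts pooled over seeds
and replicate pairs; probe→epitope is compared at inclusive/moderate,
where the two levels share a comparable signal basis.

## Validation statistics

- Enrichment: `P(X ≥ x)` hypergeometric (without replacement) and
  binomial (with replacement) tails; at pool sizes in the millions the
  two agree closely.  The positive fraction of the pool is unknown, so
  a sweep over assumed fractions is provided (`K = round(f·N)`).
- Two-proportion z-test, pooled SE, two-sided, optional continuity
  correction (off by default).
- ICC: crossed random intercepts (instrument, sample) fitted as
  variance components in a linear mixed model with optional fixed
  effects; ICC = target variance / (all components + residual);
  reliability bands poor [0, .5), moderate [.5, .75), good [.75, .9),
  excellent [.9, 1].  Negative component estimates are truncated at 0.
- ELISA calls: replicate wells averaged first; positive at OD ≥ 2.0
  (inclusive); a peptide is validated within a declared sample group
  when ≥ 25% of its sera are positive.

## Numerical and design notes

- Pooled statistics use the sample SD (ddof = 1) of the full matrix.
- BH is delegated to `statsmodels.stats.multitest` and verified against
  a brute-force step-up oracle; hypergeometric/binomial tails to
  `scipy.stats` and verified against exhaustive enumeration (N ≤ 12).
- Combined p-values are floored at 1e-300 before −log10 featureization.
- The worked geometry example, the probe-count arithmetic, smoothing,
  and the meta p-value transforms are each tested against independent
  oracles (window enumerators, closed forms, Monte-Carlo uniformity).
- Epitope p for a singleton region is the member p directly; such
  regions exist only through replicate rescue.
- Problem sizes in the test suite (200-protein simulations, 3 seeds,
  10⁵-draw null simulations) were chosen so a full run finishes in
  well under a minute while keeping binomial standard errors small
  relative to the asserted margins.

## Known limitations

- The smoothing window (±8 aa) spreads a strong epitope across ~9
  probes at 2-aa tiling, so epitope-interval estimation depends on the
  segmentation isolating the fully-binding plateau; epitopes of 11–12
  aa have only 2–3 containing probes and sit closest to the moderate
  signal cutoff.
- Per-sample BH at the epitope level becomes lenient when many strong
  regions coexist, occasionally co-calling a mouse with only chance
  elevation at a shared region (inflating K by one).
- The inclusive tier (>3 SD) is intentionally noisy; conclusions should
  rest on the moderate and restrictive tiers, which is also where
  replicate reproducibility is high.
- The ICC fit inherits MixedLM's behaviour near variance boundaries
  (zero components trigger convergence warnings; estimates are still
  returned and truncated at zero).
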
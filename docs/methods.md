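# Methods

This note documents the statistical model behind `mottle`, the semantics and
defaults of every parameter that matters, the numerical choices made where
the design was genuinely open, and what the synthetic benchmarks do and do
not demonstrate.

## Model overview and assumptions

`mottle` estimates the substitution distance D (expected substitution events
per site, multiple hits included) between two nucleotide sequences. The
estimator rests on three ideas:

1. **Origin exclusion.** Every position is an *origin* whose flanking
   fragments (forward: the next `flank_size` bases 3'; reverse: the reverse
   complement of the 5' side) are mapped to the other sequence. Because the
   origin base is excluded from the fragment, whether the two origin bases of
   a mapping match is a Bernoulli observation of local identity that no
   seeding or alignment step ever looked at — it is immune to both false
   seeding and over-alignment bias.
2. **True identity regression.** Windowed alignment statistics (GC-corrected
   identity, indel fraction) are informative but biased; origin match states
   are unbiased but binary. A gradient-boosted tree constrained to be
   monotonically increasing in identity and decreasing in indel fraction
   regresses the match state on the statistics, yielding a calibrated
   *true identity* surface: the estimated proportion of matching origins at
   each statistic combination.
3. **Homologous/null separation.** Mappings are a mixture of genuine
   homologies and chance hits. Alignments are clustered in the stabilised
   (identity, indel, true identity) space into two centres, the null centre's
   true identity pinned at the chance value. The Jukes–Cantor (JC) model
   converts the homologous cluster's mean true identity to D.

Assumptions inherited from JC: substitutions are uniform across the four
bases and sites are i.i.d. The geometric run-length model for indels assumes
independent per-site indel events. Homology is assumed collinear at fragment
scale (no attempt to stitch rearrangements; mappings on either strand are
handled, but each fragment pair is treated independently).

## Pipeline stages and parameters

Units: lengths in bases, window sizes in alignment columns, distances in
substitutions per base. All parameters live on `MottleConfig` and can be set
from CLI flags or a `key=value` config file.

### Fragmentation and mapping

- `flank_size` (default **100**): fragment length. Chosen from the middle of
  the short-read range (~50–300 bp) that fragment mappers are designed for:
  long enough that a true neighbour outranks 10^4 decoys even at ~0.4
  sub/bp, short enough that indels rarely shift a whole fragment.
- `top_n` (default **2**): neighbours returned per fragment by Mottle-map.
  One hit recovers the homolog; a second provides the null population that
  the clustering needs. Raising it grows runtime linearly and mostly adds
  null mappings.
- Mottle-map embedding: bases map to the complex plane with bonding pairs
  opposite (G→+1, C→−1, A→+i, T/U→−i); each axis is divided by the mean of
  its absolute values (floor `eps_axis = 1e-12` so all-purine/all-pyrimidine
  fragments do not divide by ~0); an unnormalised forward FFT moves the
  embedding to frequency space (tolerating small indel-induced frame
  shifts); vectors are scaled to unit L2 norm, after which Euclidean
  distance is the dissimilarity. The axis correction uses the mean of
  **absolute** values: a plain signed sum can be arbitrarily close to zero
  and explode the quotient. The FFT normalisation convention is irrelevant
  to neighbour rankings after the unit-norm step but is fixed for
  reproducibility. Neighbour ties are broken by ascending reference origin
  coordinate so results are independent of input order. The search is exact
  (blocked float32 Gram matrix); no approximate index is used — the tool
  targets small, highly divergent sequences, not genome-scale indexing.
- Both mapping directions (A fragments onto B, B onto A) are computed from
  one distance matrix and pooled; duplicated reciprocal pairs are collapsed
  onto a direction-independent canonical key. This makes
  `estimate_distance(A, B)` and `estimate_distance(B, A)` identical by
  construction.
- External mappers plug in via exported fragment FASTA and SAM
  (`--mapper sam:FILE[,FILE2]`). CIGAR strings are used only for the
  reference span; regions are re-aligned internally so all downstream
  statistics are mapper-independent. Unmapped records are dropped; secondary
  and supplementary mappings are kept.

### Alignment processing

- Needleman–Wunsch global alignment (Biopython's `PairwiseAligner`) with
  `match=+1, mismatch=−1, gap_open=−2, gap_extend=−1` (a gap of length k
  costs `gap_open + (k−1)·gap_extend`). Global alignment is used because a
  representative stretch of homology adjacent to the origin is wanted; the
  score scheme is a conventional affine choice — the method is insensitive
  to it because identity, not score, feeds the statistics. Of co-optimal
  alignments the aligner's first enumerated one is taken, deterministically.
- `leading_gap_n` (default **5**): alignments with a gap in the first 5
  origin-adjacent columns are discarded, since such gaps may shift the
  homologous frame of the origin itself.
- Truncation: the first `window` (default **50**) columns define a binomial
  null for the match count (the first window's match fraction is
  Laplace-clamped to `[1/(w+2), 1−1/(w+2)]` to avoid a degenerate
  distribution at 0% or 100% identity). A window then slides by one column;
  the first window whose match count leaves the central `binthres`
  (default **0.75**) probability mass of that binomial clips the alignment
  at the window's start. `binthres` is interpreted as the central acceptance
  mass of the two-tailed test (i.e. significance 0.25); with ~50-column
  windows this tolerates ordinary sampling noise while cutting genuine
  identity discontinuities within about one window of the changepoint.
- `min_clipped` (default **100**): alignments shorter than this after
  clipping are discarded; the same floor is applied to unclipped alignments,
  since anything shorter carries fewer than two whole windows and produces
  unstable per-alignment variances.
- Window statistics are taken on non-overlapping `window`-column tiles of
  the surviving columns (trailing partial tile dropped): raw identity
  (matches over unambiguous non-gap columns), GC-corrected identity
  `0.25 + 0.75·max(0, (raw − e)/(1 − e))` with `e` the chance match rate
  from the window's per-side base composition (so chance renormalises to
  0.25, the value the stabilising transform expects), and indel fraction
  `p = 1 − q` with `q` the fraction of adjacent non-gap pairs without
  intervening gap columns. Columns containing ambiguity codes are excluded
  from match counts and denominators and count as gaps for indel purposes —
  the least-bias treatment of Ns.

### True identity and clustering

- Stabilising transform: `arcsin(2(max(p,l)−l)/(1−l) − 1)·(2/π)`, mapping
  `[l, 1]` onto `[−1, +1]` with the chance level `l` (0.25 for identities, 0
  for indel fractions) at exactly −1. The 2/π scaling is what makes the
  stated endpoints exact; a 1/(2π) scaling cannot place chance at −1 and was
  rejected.
- GBDT (`lightgbm`): `ntrees=100`, `nleaves=32`, `learn_rate=0.1`,
  `subsamp=1.0`, monotone constraints (+identity, −indel), binary objective,
  deterministic single-threaded training seeded from the pipeline seed.
  `prior_size=10` is realised as pseudo-observations anchoring the surface's
  extremes: 10 match-labelled points at (identity 1, indel 0) and 10
  mismatch-labelled at (identity 0.25, indel 0.5). Predictions are clipped
  to [0,1], GC-corrected with the window's chance rate, and stabilised with
  l=0.25 (a true identity is a GC-corrected match proportion, chance 0.25).
  Single-class label sets fall back to a constant surface with a warning.
- **Cross-fitting.** Inside the pipeline each window is predicted by a model
  trained with the *other* half of the alignments (2 folds, alternating over
  the canonical ordering). Training and predicting on the same windows lets
  the booster partially memorise its own origin labels; cluster selection
  then correlates with the labels and inflates the homologous cluster's
  match rate — enough to turn unrelated sequences into finite distances.
  With out-of-fold predictions, selection is independent of each
  alignment's own label under the null, preserving the unbiasedness that
  origin exclusion was designed to provide. With abundant windows the two
  half-data surfaces are practically identical to the full fit, so the
  estimator at genuine homology is unaffected.
- Per-alignment summaries: means and population variances of the three
  stabilised statistics across the alignment's windows, variances floored at
  `1e-4` so single-window alignments cannot blow up the normalised distance.
- Cluster distance: the per-dimension standardised difference
  `(mean − centre)/var`, combined Euclidean. The variance (not the standard
  deviation) is kept as the denominator, matching the published parameter
  scale; the floor above bounds it.
- Clustering: 5 free parameters (null I, D; homologous I, D, T), null T
  pinned at −1. Initialisation: the null centre takes I, D from the
  alignment whose mean true identity is closest to −1; the homologous centre
  copies the alignment at the 90th percentile of mean true identities. Loss:
  `Σ dist·weight / Σ weight` over all alignment–centre pairs with
  `weight = max(dist, eps)^(−1/binpow)` (`binpow=64`, `eps` machine
  epsilon), minimised with scipy's BFGS (`maxiter=100`). If the optimiser
  fails to improve on the initialisation, the initialisation is kept and
  `converged=False` reported. Assignment is to the nearest centre;
  equidistant alignments go to the null cluster (conservative: uncertain
  alignments stay out of the distance). `learn_mult` (0.001) and `reltol`
  (1e-20) are accepted for interface parity with the published parameter
  list; scipy's BFGS governs its own line search and uses gradient-norm
  termination, so they have no direct equivalent here.
- Final distance: the homologous cluster's mean (per-alignment, then
  averaged across alignments — clustering operates on alignments, so each
  alignment contributes one value) GC-normalised true identity I enters
  `D = −(3/4)·ln(1 − (4/3)(1−I))`; I ≤ 0.25 is reported as infinite.
- **Saturation rule.** The distance is also reported infinite, with
  `converged=False`, when the homologous cluster is empty or its raw origin
  match count is not significantly above the pooled chance match rate
  (one-sided exact binomial test, α = 0.01, fixed a priori). Origin states
  are independent of the clustering features for chance mappings, so this
  test is valid under selection; it is what makes unrelated inputs return
  `inf` rather than an arbitrary large number.

### Degenerate inputs

Sequences must exceed `flank_size + window`. Zero surviving alignments →
infinite distance. One surviving alignment cannot be clustered; it is called
homologous only if its stabilised true identity is above the midpoint (−0.5).
Identical inputs are legitimate and return ~0.

## The synthetic generator

`mottle.benchmark` provides the study conditions. `random_genome` draws
uniform i.i.d. ACGT. `mutate_sequence` applies exactly
`round(length · D)` substitution events, each choosing a site uniformly
*with replacement* and replacing the current base with one of the other
three — so multiple hits occur and the expected raw identity is exactly the
JC closed form `1/4 + 3/4·e^(−4D/3)` (verified against that closed form in
the tests). Optionally, `indel_rate` adds `round(length · rate)` indel
events after the substitutions: insertion or deletion with equal
probability, lengths geometric with mean 3 (a modest, virus-like event
length; the headline benchmark uses `indel_rate=0`).

What the generator does **not** emulate: compositional bias and GC skew,
rate heterogeneity across sites, transition/transversion asymmetry,
rearrangements, repeats, and real indel length spectra. Passing the
stability benchmark therefore shows that the estimator inverts a uniform
multiple-hit substitution process on indel-poor sequence; it does not by
itself certify accuracy on biological genomes with strong composition
structure or repeat content.

## Benchmark metrics

- `stability_curve`: for an ascending ladder of true distances, mutate the
  genome and run the tool; failures and NaN count as infinite predictions;
  predictions are clipped to [0,1] before the error. The running MAE at
  index k divides by the k+1 trials completed; the *maximum stable distance*
  is the last rung before the running MAE first exceeds the threshold (0.05
  sub/bp by convention), `None` if the first rung already exceeds it.
- `concatenate_alignments`: greedy assembly of known-divergence alignment
  candidates around a target JC distance — start at the closest candidate,
  then repeatedly add (without replacement) the candidate closest to the
  target on the opposite side of the current pooled distance, until a
  minimum length is reached or no valid candidate remains.
- `outgroup_call`: correct / incorrect / ambiguous from comparator and
  outgroup distances, NaN mapped to infinity first; inf vs inf is ambiguous.

## Problem sizes used in the checks

The package's own acceptance run uses a 5 kb random genome with thirteen
distances 0→0.6 (step 0.05) at default parameters — about 19 600 fragments
per comparison and ~20k–30k unique mappings per rung — plus a 2 kb
identical-sequence control, a 100 kb simulator calibration, and 100 planted
nearest-neighbour trials. These sizes were chosen as the smallest substrate
on which the mapping/clustering statistics are comfortably dense; accuracy
improves, and runtime grows roughly quadratically, with sequence length.

## Known limitations

- Accuracy at *low* divergence is limited by the clustering granularity: a
  few spurious alignments surviving in the homologous cluster bias D upward
  by O(10^-3) even for identical inputs.
- The brute-force mapper is quadratic in sequence length; beyond ~50 kb an
  external short-read mapper via the SAM backend is the practical route.
- Distances are pairwise only; amino-acid input, simultaneous multi-sequence
  distance, and sub-alignment isolation are out of scope.
- The truncation test's false-positive rate (1 − `binthres` per effective
  window) discards a fraction of genuinely homologous alignments at high
  divergence; survivors are slightly biased toward their first window's
  identity. The true-identity regression absorbs most, not all, of this.
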
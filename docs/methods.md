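# Methods

## Data model and input format

A peak table is an ordered list of detected compounds, each with a
first-dimension retention time (s), a second-dimension retention time
(s within the modulation period) and a sparse unit-mass spectrum
(integer m/z → relative abundance ≥ 0). The reader accepts
tab-separated text with a header row and the spectrum encoded as
`m/z:intensity` tokens; header names and both separators are
configurable because peak-detection exports vary. Abundances are kept
exactly as read — rescaling a spectrum changes neither Pearson nor
cosine similarity, so renormalisation at parse time would only obscure
provenance. Row order is preserved: a peak's index is its row index.
`rt2` is treated as within-modulation seconds; wrap-around across the
modulation boundary is not modelled because exported tables do not
encode it.

## Spectral similarity

Two spectra are compared on the union of their m/z keys, absent masses
entering as zeros: a fragment present in one spectrum and absent in the
other is evidence against a match, mirroring library-search practice.
The optional power transform maps each entry `(m, I)` to
`(m, I^a · m^b)` with defaults `a = 0.53`, `b = 1.3`. It compresses
intensity differences and amplifies heavy fragments, which is what
separates homologues that share their low-mass ions (see
`examples/spectral_transform_effect.py`). Conventions for degenerate
inputs: cosine against a zero vector is 0, Pearson of a constant vector
is 0. For threshold gating all similarities are floored at 0 —
thresholds live on a [0, 1] scale and anti-correlation is as much a
non-match as orthogonality. Raw spectra are never mutated; the
transform produces new objects (hoisted to once per table in the
matching loops, which is numerically identical to transforming per
pair).

## Anchor detection

Six matchers produce anchor sets between a reference and an aligned
table. Shared numerical choices:

* **z-scoring.** The neighbourhood and weighted-score matchers
  standardise each dimension of each table on its own mean and sample
  standard deviation (n−1). This makes the two time axes commensurable
  and, as a side effect, makes the candidate neighbourhoods invariant
  to any affine drift between the tables. Tables with fewer than two
  peaks or zero spread in a dimension are rejected with an error naming
  the dimension.
* **Neighbourhood size.** `ceil(fraction · N)` with fraction defaulting
  to 0.20 — rounding up guarantees at least one candidate for a
  non-empty table.
* **Canberra distance** uses the convention that 0/0 terms contribute 0.
* **One-to-one enforcement.** The per-reference-peak selection rules can
  let two reference peaks claim one aligned peak. Conflicts are resolved
  greedily: keep the pair with the higher selection score, break ties by
  smaller total-retention-time difference, then by lower reference
  index. This is deterministic and O(k log k); an optimal assignment
  was rejected because the selection rules are defined per reference
  peak, not as a global objective, and a duplicated aligned peak would
  corrupt the warp fit.
* **Gaussian-penalty cutoffs.** In the bidirectional-hit matcher the
  cutoffs T₁, T₂ are interpreted as lower bounds on each exponential
  penalty factor: a factor below its cutoff discards the pair, which
  turns (T, D) into an implicit search window of half-width
  `D·sqrt(−2·ln T)`. The defaults T₁ = T₂ = 0.5 give a window of
  ±1.18·D; 0 disables the gate (the exponential is always positive).
  This cutoff-on-penalty reading is this package's choice; the original
  formulation leaves the mechanism open.
* **Weighted-score matcher short-circuit.** The spectral gate is
  evaluated before the distance, and a failing pair skips the distance
  computation entirely.
* **Sequence aligner.** Both tables are sorted by total elution time;
  the local-alignment recurrence is `max(0, diag + match/mismatch,
  up + gap, left + gap)` with the match/mismatch decision made by the
  similarity threshold, traceback from the global maximum to the first
  zero cell. Match/mismatch/gap scores default to +1/−1/−1 (standard
  local-alignment convention; the source method leaves them unstated)
  and are configurable.

The neighbourhood top-similarity matcher and the combined
neighbourhood + weighted-score matcher are implemented as separate code
paths even though the latter with `w = 0` and Euclidean distance reduces
to the former; keeping them independent lets the test suite use the
reduction as a genuine cross-check (tie-breaks are aligned: candidates
are iterated in ascending-distance order with strict-improvement
argmax, and conflict resolution uses identical keys).

## Elution-order check

Anchors are filtered for consistency in total elution time
`rt1 + rt2`: any two retained anchors must order the same way, strictly,
in both tables. Equal totals count as violations — two distinct
compounds cannot co-elute identically in both dimensions after
detection, so a tie signals a misidentification. The largest consistent
subset is kept, computed as a longest strictly increasing subsequence
after sorting by (reference total ascending, aligned total descending);
the descending tie-key makes reference-total ties mutually exclusive.
LIS removes the fewest anchors of any consistent filter, and removed
pairs are reported in the log.

## Time correction

The warp is fitted per dimension, independently, through the surviving
anchors only, mapping aligned times onto the reference axis:

* `global_linear` — one least-squares line per dimension; needs at
  least two anchors at distinct aligned times.
* `piecewise_linear` (default) — linear interpolation through the
  (aligned, reference) anchor knots, duplicate aligned times averaged,
  linear extrapolation from the outermost segment, one knot degrading
  to a constant offset. It is exact at the anchors and follows drift
  that turns nonlinear late in the temperature program, which is why it
  is the default; the global line is retained for when a strictly
  affine correction is wanted (e.g. parameter recovery).

Corrected times that fall below zero are clamped to 0 with a warning
rather than dropping peaks. Warping never changes peak count, order,
labels or spectra. Column-bleed rectangles can be excluded from both
tables before matching (closed intervals). The retention-index
transform interpolates each dimension's ladder (≥ 2 strictly increasing
(rt, index) points) linearly, extrapolating the end segments — the
linear temperature-programmed convention.

## Evaluation

The two-sample Kolmogorov–Smirnov statistic per dimension is the fit
metric (`scipy.stats.ks_2samp`; the statistic is the exact supremum
over pooled points). No p-value is reported — the statistic is used as
a distance, not a test. Confusion counts score a predicted anchor set
against a known correspondence: a predicted pair is TP if it agrees
with the truth and FP otherwise (wrong partner, or any partner for an
absent compound); FN is a true pair with no prediction; TN an absent
compound left unmatched. Precision, recall and F1 with an undefined
denominator are reported as undefined (`None`), never as 0.
`F1 = TP/(TP + (FN+FP)/2)` equals the harmonic mean `2PR/(P+R)`
whenever both are defined; the suite asserts this identity numerically.

## Synthetic benchmark

The generator fabricates what the tool consumes — exported peak tables
— not chromatography: no peak shapes, modulation or co-elution.
Spectra are random sparse fragment sets (6–15 fragments over m/z
29–350, one dominant ion) rejection-sampled to pairwise raw cosine
< 0.5 so that correct matches are unambiguous by construction.
Reference tables draw retention times uniformly over (60–2400) s ×
(0.5–5.5) s and sort by total elution time. The distortion applies a
per-dimension affine warp plus Gaussian jitter, Bernoulli dropout,
spurious insertions with fresh (dissimilar) spectra, and multiplicative
log-normal noise on fragment intensities; the ground truth records the
surviving correspondence and the generating warp.

Preset study conditions (150 peaks per table by default):

* `same_system` — constant offsets 8 s / 0.15 s, jitter 0.3 s / 0.01 s,
  3% spectral noise, no dropout or insertions: consecutive runs on one
  column set, where every compound is present in both runs.
* `cross_system` — affine drift (1.003·rt1 + 18 s; 0.97·rt2 + 0.3 s),
  jitter 0.5 s / 0.02 s, 3% dropout, 3 insertions, 5% spectral noise: a
  column replacement in both dimensions. The dimension-1 drift reaches
  ≈25 s at the end of the program, sized to the static-window matcher's
  documented ±25 s setting; dimension-2 drift dominates the modulation
  scale, as column replacement does.

Because the paired K-S statistic is granular at 1/n, the improvement
property (K-S after ≤ before) is only informative when the systematic
drift exceeds the ECDF noise floor contributed by dropout and
insertions; the preset magnitudes are chosen so that holds, which is
also why `same_system` carries no dropout. What passing these
benchmarks does **not** show: robustness to deconvolution-deformed
spectra, dense co-eluting regions where several true candidates exceed
the threshold, or qualitative sample-to-sample composition differences
beyond random dropout. Default RNG seed is 42 throughout; all
randomness flows through `numpy.random.default_rng`.

## Known limitations

* Pairwise only: one aligned table against one reference. Multi-sample
  clique building across more than two chromatograms and iterative
  reference reduction over a whole dataset are out of scope; a dataset
  is aligned sample-by-sample against a fixed reference.
* The warp family is monotone per-dimension (line or piecewise line);
  two-dimensional coupled warps and raw-signal warping are not
  modelled.
* The K-S statistic conflates warp error with qualitative composition
  differences; on real data it never reaches zero.
* Greedy conflict resolution is order-optimal per the selection scores
  but not globally optimal; with well-separated spectra the difference
  is immaterial (the brute-force oracles in the test suite agree
  exactly on small instances).
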
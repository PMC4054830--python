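# Methods

## Problem and model

Given a protein sequence, every arginine (or lysine) residue is a candidate
methylation site. The predictor is a binary classifier over centred
11-residue windows (half-width ξ = 5): the window is encoded as a
346-dimensional pseudo-amino-acid-composition vector and scored by an
RBF-kernel SVM with decision threshold 0 (a decision value of exactly 0 is
called positive; the boundary side is a convention, fixed here and tested).

## Benchmark curation

Windows overhanging a terminus are completed by repeating the nearest
existing residue (the terminal one). Duplicate peptide strings within a
label set are reduced to the first occurrence in input order — the survivor
is unspecified in the original description, so first-kept was fixed for
determinism. Peptides occurring with both labels are removed from both sets.
Duplicates arising from the same protein at different positions are treated
exactly like cross-protein duplicates. Windows containing non-standard
letters (X, B, Z, U, …) are skipped with a logged warning. Positions are
1-based everywhere in I/O and internal records.

The negative:positive ratio in curated methylation benchmarks is roughly
7:1, so the default negative partition uses seven subsets (sizes differing
by at most one after a seeded permutation; default seed 0, documented so
published runs reproduce).

## Feature encoding (Ω = 346)

Segments, 1-based half-open: pssm [1,221), grey [221,281), aaf [281,336),
disorder [336,347).

* **Profile (220).** Provider contract: something that returns an 11×20 raw
  score matrix for a window, with amino-acid columns in alphabetical
  one-letter order. The production provider parses ASCII PSSM tables from an
  iterative profile search run on the **full protein** (three iterations,
  E-value cutoff 0.001), remapping the tool's native column order
  (A,R,N,D,…) to alphabetical; rows are sliced per window with the same
  terminal-repeat rule as window extraction. Searching with the 11-mer
  itself instead of the full protein would yield degenerate profiles, so
  full-protein profiling is the default. The offline fallback provider uses
  BLOSUM62 rows per window residue — deterministic, database-free, and used
  throughout the tests. Raw scores are squashed by the standard sigmoid;
  values saturating in double precision are nudged to the nearest
  representable number inside (0,1) so the open-interval contract holds.
* **Grey GM(1,1) (60).** Per profile column, the least-squares solution of
  the 10×3 system built from the column's cumulative sums and first
  differences. Singular normal equations (constant columns, which do occur
  for low-complexity windows under the fallback provider) take the
  minimum-norm solution via `numpy.linalg.lstsq`, so a constant column
  encodes as (0,0,0) rather than failing. No extra scaling is applied to
  grey features beyond the classifier's global rescaling.
* **Atchley factors (55).** The five-factor 2005 solution of the amino-acid
  metric problem, transcribed once into
  `src/methylsite/data/atchley_factors.tsv` (source and transcription date
  recorded in the file header; a checksum test guards against silent
  edits). Ordering is position-outer, factor-inner.
* **Disorder (11).** Per-residue scores in [0,1] computed on the full
  protein and sliced per window; overhanging window positions reuse the
  terminal residue's score (the external description leaves filled
  positions undefined; terminal-score reuse mirrors the sequence fill
  rule). The production provider reads an external disorder predictor's
  two-column output. The offline fallback averages the TOP-IDP per-residue
  disorder propensity over a centred 9-residue smoothing window and min-max
  maps the scale's range onto [0,1] — it preserves the qualitative
  disorder signal (P/E/K-rich disordered vs W/F/I-rich ordered) but is not
  a substitute for a trained disorder predictor's accuracy.

## Classifier and tuning

`sklearn.svm.SVC` (the libsvm binding) with the RBF kernel. Features are
linearly rescaled per dimension to [0,1] using training-set min/max
(constant features map to 0); scaling parameters are stored in the model
archive together with (c, γ), the feature schema version and a training-set
fingerprint. The default grid is the conventional coarse search grid
log₂c ∈ {−5,−3,…,15}, log₂γ ∈ {−15,−13,…,3}; ties break toward smaller c,
then smaller γ. Tuning supports stratified k-fold (default 5, seeded) and
the jackknife. The end-to-end experiments tune **under the jackknife**, for
a substantive reason: leave-one-out briefly unbalances the classes by one
sample, and underfit cells (small c and γ, where the kernel is nearly
constant and every point is a support vector) collapse onto the majority
class in exactly that regime — stratified k-fold scores such cells highly
and cannot see the failure.

## Evaluation

Leave-one-out over the pooled positives + one negative subset, model
retrained for each held-out sample; metrics from the pooled class-total
counts; the seven per-subset metric sets are averaged arithmetically at
full precision (rounding only at display). MCC is set to 0 when its
denominator vanishes (single-class prediction) and clamped to [−1,1]
against floating-point overshoot at the exact limits. An empty class makes
Sn or Sp undefined; the report carries an explicit marker (None) rather
than a silent 0. Averages over reports propagate the marker.

One published worked example prints MCC = 0.63 for counts
(N⁺=1, N⁻=10, N₋⁺=0, N₊⁻=2), but the class-total formula — and the
equivalent TP/TN/FP/FN formula — gives 0.52 from those counts, while the
printed Sp = 0.80 and Acc = 0.82 do follow; the tests assert the recomputed
value. Similarly, a printed average MCC of 52.74% is consistent with
averaging full-precision per-subset values, not the rounded table column;
averaging here is defined over full-precision values.

## Synthetic benchmark

The generator emulates the study conditions offline: proteins drawn
uniformly over the 20 residues (mean length 120, sd 10%, floor 30), a
fraction pos_fraction = 1/8 of centre-residue sites annotated positive
(echoing the ~1:7 class ratio), and a glycine-rich motif context planted
around positives — each flank position within the window is replaced with
probability `signal_strength` by a letter from the motif alphabet "GGA".
The alphabet has three letters rather than pure G so planted windows stay
distinct under duplicate winnowing even at full signal. Synthetic profiles
are the fallback rows plus Gaussian noise with sd 2.0·(1−signal_strength),
seeded per (window, seed); disorder tracks are seeded random walks clamped
to [0,1]. Uniform residue background keeps the generator simple and exactly
seedable; it does not reproduce real amino-acid composition, real profile
covariance structure, or biological motif specificity. Passing recovery
tests therefore demonstrate that the pipeline's plumbing and learning
machinery work — not that the reported real-data accuracies transfer.

## Problem sizes used in tests

The end-to-end recovery experiments use 100 synthetic proteins yielding a
balanced 40+40 dataset, a 3×3 (log₂c, log₂γ) subgrid tuned under
leave-one-out, and leave-one-out final evaluation; the null condition
repeats this over 5 seeds. These sizes give stable pass/fail behaviour
(strong-signal accuracy ≈ 0.96, null accuracy ≈ 0.5) with a fast default
test run. The exhaustive metric-equivalence oracle enumerates every
confusion table with class totals up to 30.

## Known limitations

* The published real-data benchmark (1,481 Arg / 1,884 Lys samples from a
  2013 protein-database release) and its jackknife accuracies are not
  reproducible without that database, the original profile-search setup and
  the external disorder predictor; this package reproduces the method and
  its desk-checkable quantities, and validates the pipeline on synthetic
  data.
* The fallback profile and disorder providers are deterministic stand-ins
  with the right shapes and qualitative behaviour, not re-implementations
  of the external tools.
* No probability calibration; decision values are margins, comparable only
  within one model.
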
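# methylsite

Prediction of arginine (Arg/R) and lysine (Lys/K) methylation sites in
proteins from sequence alone.

Protein methylation is a major post-translational modification: Arg- and
Lys-methylation regulate gene expression and are implicated in cancer,
cardiovascular and neurodegenerative disease. Experimentally mapping which
of a protein's R/K residues can be methylated is slow, and the space of
candidate local contexts is astronomically large (20^10 ≈ 1.02×10¹³ distinct
11-residue windows around a fixed centre), so sequence-based predictors are
the practical route. This package is for computational biologists who want a
transparent, scriptable implementation of a classical
pseudo-amino-acid-composition (PseAAC) site predictor — benchmark curation,
feature encoding, SVM training and honest evaluation included.

## Method

Every R (or K) in a protein defines a candidate site, represented by the
centred window **P** = R₋₅…R₋₁ C R₊₁…R₊₅ (length 2ξ+1 = 11 for ξ = 5;
windows overhanging a terminus repeat the terminal residue). Each window is
encoded as a 346-component PseAAC vector
**P** = [ψ₁ … ψ₃₄₆]ᵀ with Ω = 220 + 60 + 55 + 11:

1. **Evolutionary profile (220):** an 11×20 position-specific scoring
   matrix M⁰ (from an iterative profile search, or an offline BLOSUM62
   fallback), squashed elementwise by the sigmoid m = 1/(1+e^(−m⁰)) and
   read out type-outer/position-inner.
2. **Grey-model descriptors (60):** for each profile column j, the GM(1,1)
   least-squares triple (a1ⱼ, a2ⱼ, bⱼ) solving Bⱼx ≈ Uⱼ, where row k−1 of
   Bⱼ is [−m(k), −Σᵢ₌₁^{k−1} m(i) − 0.5·m(k), 1] and Uⱼ holds first
   differences (minimum-norm solution when BᵀB is singular).
3. **Atchley factors (55):** five physicochemical factor scores (polarity,
   secondary structure, molecular volume, codon diversity, electrostatic
   charge) per window residue.
4. **Disorder (11):** per-residue intrinsic-disorder scores in [0,1],
   computed on the full protein and sliced per window (external predictor
   output, or a smoothed propensity-scale fallback).

An RBF-kernel SVM (class labels ±1, decision threshold 0) is tuned by grid
search over (c, γ) and evaluated by the jackknife (leave-one-out) test.
Because negatives outnumber positives roughly seven to one, the negative set
is randomly split into seven near-equal subsets; the positives are paired
with each subset in turn and per-subset metrics are averaged. Quality is
reported as Sn, Sp, Acc and MCC in the class-total form

    Sn = 1 − N₋⁺/N⁺,  Sp = 1 − N₊⁻/N⁻,
    Acc = 1 − (N₋⁺+N₊⁻)/(N⁺+N⁻),
    MCC = (1 − (N₋⁺/N⁺ + N₊⁻/N⁻)) / √((1 + (N₊⁻−N₋⁺)/N⁺)(1 + (N₋⁺−N₊⁻)/N⁻)),

which is algebraically identical to the textbook TP/TN/FP/FN formulas.

## Worked example

A seeded synthetic benchmark with a planted glycine-rich motif around
positive Arg sites exercises the full pipeline offline
(`examples/03_tune_and_evaluate.py`):

```
balanced dataset: 40 positives, 40 negatives, 346 features
best cell: c=0.5, gamma=0.015625 (LOO acc 0.963)
jackknife metrics: Sn=0.975 Sp=0.950 Acc=0.963 MCC=0.925
```

With a strong planted signal the jackknife recovers it almost perfectly:
39/40 positives and 38/40 negatives are called correctly by models that
never saw the tested sample. Metric bookkeeping on published whole-protein
scans (`examples/05_metrics_worked_examples.py`):

```
P62805 Arg scan: N+=1 N-=13 N-+=0 N+-=1 -> Sn=1.00 Sp=0.92 Acc=0.93 MCC=0.68
half of each class wrong: N+=10 N-=20 N-+=5 N+-=10 -> Sn=0.50 Sp=0.50 Acc=0.50 MCC=0.00
```

The remaining examples cover benchmark curation (`01`), feature encoding
(`02`) and whole-protein scanning (`04`). The same stages are scriptable
from a shell via the thin CLI:

```bash
methylsite synth --out-fasta syn.fasta --out-annotations syn.tsv --seed 1
methylsite curate --fasta syn.fasta --annotations syn.tsv --residue-type R --out bench.tsv
methylsite encode --benchmark bench.tsv --fasta syn.fasta --out features.tsv
methylsite tune --features features.tsv
methylsite train --features features.tsv --out model.joblib
methylsite predict --fasta syn.fasta --mode R --model model.joblib --out calls.tsv
```

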
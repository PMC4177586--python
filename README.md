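# lncclass

Alignment-free discrimination of long non-coding RNAs (lncRNAs) from
messenger RNAs (mRNAs) in transcript FASTA files — no reference genome,
annotations or protein databases required. The intended users are
transcriptomics groups working with *de novo* assembled transcripts,
including long-read (454/PacBio-style) assemblies whose homopolymer indel
errors break reading-frame-based classifiers.

## Method

Each transcript of length *l* is scanned with sliding windows of size
*k* = 1..5 advancing one nucleotide at a time. For pattern *i* of size *k*,
with occurrence count *c_i* and *s_k = l − k + 1* valid window placements,
the feature is the calibrated usage frequency

```
f_i = (c_i / s_k) · w_k ,    w_k = 4^(k − k_max)
```

giving 4 + 16 + 64 + 256 + 1024 = 1,364 features at the default k range.
The weight *w_k* up-weights longer patterns so all k sizes contribute on a
comparable scale (a mononucleotide sits near frequency 0.25, a specific
5-mer near 0.001). Features are scaled to [0, 1] with training-set minima
and maxima and fed to an RBF-kernel support vector machine; *C* and *gamma*
come from an exhaustive grid search scored by stratified 10-fold
cross-validation. The SVM decision value *d* is reported per transcript:
*d* > 0 ⇒ mRNA, *d* ≤ 0 ⇒ lncRNA (cutoff configurable), with |*d*| acting
as confidence.

Because one-nucleotide-step window counts barely move when a single base is
inserted or deleted, the features — unlike codon- or frame-based ones — are
robust to homopolymer indel sequencing errors. The package ships a
simulator for exactly that error mode (single-base indels placed in the
longest homopolymer runs at a chosen rate), a Wilcoxon rank-sum scan for
differential k-mer usage between the classes, the standard five-metric
evaluation (sensitivity, specificity, PPV, NPV, accuracy), and a seeded
synthetic corpus generator so the whole pipeline trains and tests at desk
scale with no downloads.

## Worked example

```python
from lncclass import (CorpusSpec, confusion, enumerate_patterns,
                      featurize_records, generate_corpus, metrics,
                      predict, train_classifier)
from lncclass.svm import COARSE_C_GRID, COARSE_GAMMA_GRID

corpus = generate_corpus(CorpusSpec(n_per_class=150, seed=4,
                                    length_range=(300, 1500)))
table = enumerate_patterns(1, 5)
pos_X, pos_ids = featurize_records(corpus.coding, table)
neg_X, neg_ids = featurize_records(corpus.noncoding, table)
bundle, search = train_classifier(pos_X[:100], neg_X[:100], seed=0,
                                  C_grid=COARSE_C_GRID,
                                  gamma_grid=COARSE_GAMMA_GRID, folds=5)
```

Running `python examples/02_train_and_classify.py` (the script above plus
held-out scoring) prints:

```
grid search: C=0.5 gamma=0.00195312 5-fold CV accuracy=1.000
held-out: sensitivity=1.000 specificity=1.000 accuracy=1.000
example call: coding_00100 decision=+0.847 -> mRNA
```

The grid search line shows the selected hyperparameters and the
cross-validated accuracy on the balanced 100-per-class training set; the
held-out line scores 50 unseen transcripts per class; the last line is one
prediction — a positive decision value called mRNA. The other scripts in
`examples/` demonstrate featurization, indel simulation, the differential
k-mer scan and the robustness curve; `examples/05_robustness_curve.py`
prints accuracy 1.000 at indel rates 0, 1, 2 and 3 per 100 bases,
illustrating the flat robustness profile.

## Command line

The same pipeline is exposed as a thin CLI:

```
lncclass make-fixtures --n 500 --seed 1 --outdir fixtures/
lncclass train fixtures/coding.fa fixtures/noncoding.fa --out-model model.joblib
lncclass predict transcripts.fa --model model.joblib -o predictions.tsv
lncclass simulate-indels --rate 0.02 --seed 1 in.fa out.fa
lncclass evaluate --truth fixtures/truth.tsv --pred predictions.tsv
```

Exit codes: 0 success, 2 usage error, 3 input/format error, 4
model/feature-space mismatch.

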
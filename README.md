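# qsppred

Prediction and sequence analysis of bacterial **quorum-sensing peptides
(QSPs)** — the short oligopeptide signals (autoinducing peptides) that
Gram-positive bacteria secrete to coordinate density-dependent behaviours
such as competence, sporulation and biofilm formation. Distinguishing
these signals from ordinary short peptides matters for anti-virulence
("quorum quenching") work, and QSPs turn out to carry a strong sequence
signature: they are short (typically 5–30 residues), enriched in aromatic
residues (Trp, Phe, Tyr) and Cys/Asn, depleted in Asp/Glu, and show
terminal preferences (Ser near the N-terminus, Phe near the C-terminus).

The package is aimed at computational microbiologists and peptide
designers. It provides:

* an **RBF-kernel SVM classifier** over fixed-length sequence encodings —
  amino-acid composition (AAC, 20-d), dipeptide composition (DPC, 400-d),
  terminal one-hot binary profiles (N5C5Bin, 200-d), AAindex-style
  physicochemical descriptors with top-k screening, and hybrids — with
  seeded stratified 10-fold cross-validation, (C, γ) grid search and
  Sn/Sp/Acc/MCC/ROC-AUC reporting;
* a **physicochemical panel** (length, aromaticity, instability index,
  pI, molecular weight, GRAVY) per peptide and per set;
* **motif scanning** with PROSITE-style bracket patterns (nine QSP motifs
  bundled) and peptide-level PPV / % coverage evaluation;
* **compositional analyses**: pooled composition, fold change against a
  background proteome, two-sample positional enrichment at the termini;
* **design tools**: exhaustive single-position mutant scoring
  (QSPepDesign/MutGen) and sliding-window protein scanning
  (QSPepMap/ProtFrag);
* a seeded **synthetic-data generator** reproducing the reported
  statistical structure of the curated QSP/non-QSP corpus, so the whole
  pipeline is testable without redistributing the original datasets.

## Model

A peptide `s` of length `L` is mapped to a feature vector `x(s)`
(e.g. AAC: `x_a = count(a)/L`), min–max scaled to [0, 1] on training data,
and classified by a soft-margin SVM with kernel
`K(x, x') = exp(−γ‖x − x'‖²)`. Hyper-parameters (C, γ) are selected on a
log₂ grid by pooled 10-fold cross-validated accuracy; performance is
summarized by

    Sn = 100·TP/(TP+FN)      Sp = 100·TN/(TN+FP)
    Acc = 100·(TP+TN)/N      MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))

at decision threshold 0, plus the threshold-independent ROC AUC. See
`docs/methods.md` for the encodings, the evaluation protocol (including
why composition-matched scrambled negatives require pair-grouped folds),
and the generator's design.

## Worked example

Train an AAC model on a synthetic study-sized dataset and rank the
single-position mutants of a competence-stimulating-peptide-like sequence:

```python
from qsppred import QspClassifier, CVConfig, EncodingSpec
from qsppred.fixtures import generate, FixtureSpec
from qsppred.seqio import Peptide

pos, neg = generate(FixtureSpec(seed=1))          # 220 QSP-like + 220 background
clf = QspClassifier.from_peptide_sets(
    pos, neg, EncodingSpec("AAC"),
    cv=CVConfig(n_folds=10, seed=1,
                c_grid=(0.5, 8.0, 128.0), g_grid=(0.0078125, 0.125, 2.0)),
)
res = clf.fit()
print(res.summary())
```

```
QSP classifier — RBF-SVM fit summary
====================================================
Encoding:            AAC (20 features)
Peptides:            440 (220 positive)
CV folds / seed:     10 / 1
Selected C, gamma:   8, 0.125
----------------------------------------------------
CV sensitivity:       93.18 %
CV specificity:       95.45 %
CV accuracy:          94.32 %
CV MCC:               0.887
CV ROC AUC:           0.982
Confusion (pooled):  TP=205 TN=210 FP=10 FN=15
Per-fold accuracy:   95 98 93 86 91 93 93 100 95 98
====================================================
```

The fit selected C = 8, γ = 0.125 and classifies ~94% of held-out
peptides correctly (MCC 0.887: strong balanced agreement; AUC 0.982:
near-perfect ranking). Mutant design on a new peptide:

```python
out = res.design(Peptide("pep1", "SGSLSTFFRLFNRSFTQA"))
print(out.head(3)[["decision_value", "label", "seq"]])
```

```
                decision_value     label                 seq
peptide_id
pep1|16Q>C            2.424988  positive  SGSLSTFFRLFNRSFTCA
pep1|16Q>F            2.403905  positive  SGSLSTFFRLFNRSFTFA
pep1|16Q>W            2.401909  positive  SGSLSTFFRLFNRSFTWA
```

The top-ranked substitutions replace the lone Gln with Cys/Phe/Trp —
exactly the residues the positive class is enriched for, so the model has
learned the intended composition signal.

The same functionality is available from the shell:

```bash
qsppred fixtures --n-pos 220 --n-neg 220 --seed 1 --out-dir data/
qsppred physprop --in data/pos.fa --out props.tsv
qsppred cv --pos data/pos.fa --neg data/neg.fa --features aac+dpc --quick-grid
qsppred train --pos data/pos.fa --neg data/neg.fa --features aac --model m.joblib
qsppred map --model m.joblib --in protein.fa --window 12
qsppred motifeval --pos data/pos.fa --neg data/neg.fa
```

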
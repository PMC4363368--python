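# Methods

## Problem and scope

Quorum-sensing peptides (QSPs) are short oligopeptide signals — mostly from
Gram-positive bacteria — that regulate density-dependent behaviours such as
competence, sporulation and biofilm formation. `qsppred` classifies a
candidate peptide as QSP or non-QSP from sequence alone and provides the
descriptive analyses around that task: residue composition and fold-change
contrasts, terminal positional enrichment, bracket-class motif scanning,
and a six-property physicochemical panel.

The classifier is a C-SVM with an RBF kernel
`K(x, x') = exp(-γ‖x − x'‖²)` over fixed-length encodings of the
variable-length peptide. Nothing about the model is peptide-specific; the
scientific content lies in the encodings, the evaluation protocol and the
data structure, all described below.

## Feature encodings

All encodings index the 20 standard residues in fixed alphabetical order
(ACDEFGHIKLMNPQRSTVWY); dipeptides use the 20×20 row-major product.

* **AAC** (20): residue fractions, `count(a)/L`. Rows sum to 1.
* **DPC** (400): overlapping dipeptide fractions, `count(ab)/(L−1)`.
  Order-sensitive — `ACAC` and `AACC` encode differently even though their
  AAC is identical.
* **N5Bin / C5Bin / N5C5Bin** (100/100/200): one-hot blocks for the first
  and/or last five residues, N blocks before C blocks. For peptides of
  length between `max(k_N, k_C)` and `k_N + k_C` the two windows overlap;
  we allow the overlap rather than pad, because padding would introduce a
  21st "blank" symbol foreign to every other encoding. Shorter peptides
  are unencodable and are reported as such, never silently dropped.
* **Physico** (k): the mean per-residue value of k selected AAindex-style
  scales. The mean is the simplest length-invariant reduction of a
  per-residue scale and makes the feature order-free.
* **hybrid**: concatenation of any of the above in declared order.

**Index screening.** `select_top_indices` ranks every scale in an
`AAIndexTable` by the stratified 10-fold CV accuracy of a one-dimensional
RBF-SVM using only that scale (C = 1, γ = 'scale'), and returns the top k
(default 10), ties broken lexically by accession so the ranking is
deterministic. Scores are seeded, so the full screen is reproducible.

**Scale availability.** The AAindex database itself is not distributed
with the package. `aaindex.curated_table()` assembles genuine literature
scales available at run time from Biopython's ProtParam data
(Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity, Vihinen
flexibility, Janin and Engelman transfer energies) plus residue mass,
aromatic-indicator and nominal-charge scales;
`aaindex.synthetic_screening_table(n, seed)` generates clearly-labelled
synthetic pseudo-scales so the screening machinery can be exercised at the
customary 544-index scale. A reader/writer for the AAindex1 flat-file
format lets users load a real release if they have one. The twelve
best-performing accessions reported for QSPs (helix propensities, coil and
turn frequencies, pK-C, side-chain gyration radius, polar requirement)
ship as an identifier preset in `aaindex.CANDIDATE_ACCESSIONS`.

## Feature scaling

All features are min–max scaled to [0, 1]. Scaling ranges are learned on
the training folds only and reapplied to held-out folds and to new
peptides at prediction time; with mixed-scale hybrids (fractions next to
molecular masses) the RBF kernel is otherwise dominated by the
largest-range block.

## Model selection and evaluation

* **Folds**: stratified, seeded, k = 10 by default. With pair-structured
  data (see scrambled negatives) `StratifiedGroupKFold` keeps a group's
  members in one fold.
* **Grid**: C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, …, 2³} (log-2 steps of 2)
  by default. Selection maximizes pooled out-of-fold accuracy; ties break
  by higher MCC, then smaller C, then smaller γ (preferring the least
  complex model among equals).
* **Threshold-dependent metrics** at decision threshold 0 (the SVM margin
  midpoint): Sn = 100·TP/(TP+FN), Sp = 100·TN/(TN+FP),
  Acc = 100·(TP+TN)/N, and MCC on its standard [−1, 1] scale. A zero
  marginal makes MCC undefined; it is then reported as 0 with an explicit
  flag rather than aborting a batch run.
* **Threshold-independent**: ROC AUC (equivalently the Mann–Whitney pair
  statistic, ties counted ½), computed from the pooled out-of-fold
  decision values.
* The final model is refit on all data at the selected (C, γ). The whole
  pipeline is deterministic given the seed.

## Scrambled negatives and twin leakage

The composition-matched negative strategy scrambles each positive
(seeded Fisher–Yates), preserving its residue multiset exactly. AAC and
every other order-free feature of a peptide and its scramble are therefore
bit-identical, and the two classes should be exactly indistinguishable to
a composition-based classifier: the honest result is chance-level
accuracy.

Naive k-fold CV does **not** produce that result. If a peptide is held out
while its scramble twin remains in training, the twin contributes an exact
duplicate of the test vector with the opposite label; paired duplicates
inside the training set cancel each other, so the un-cancelled twin
dominates the test point's decision value and the model *anti-predicts*
systematically — accuracy far below 50% at every (C, γ) we measured.
The package therefore evaluates the scrambled-negative strategy with
grouped folds (each peptide/scramble pair treated as one group), which
restores the chance-level outcome. Both behaviours are covered by tests,
since the anti-learning mode is an easy trap for users building their own
scramble controls.

## Physicochemical panel

Per peptide: length, aromaticity (fraction of F/Y/W), Guruprasad
instability index `II = (10/L)·Σ DIWV(xᵢ, xᵢ₊₁)` with II < 40 read as
stable, isoelectric point, average molecular weight, and GRAVY (mean
Kyte–Doolittle hydropathy). Reference tables — the 400-entry DIWV matrix,
the hydropathy scale, Bjellqvist pK values and average residue masses —
are imported from Biopython's ProtParam data at run time, keeping the
package consistent with ExPASy ProtParam conventions (average rather than
monoisotopic masses; residue-specific N/C-terminal pK adjustments).

pI is found by bisection of the Henderson–Hasselbalch net charge on
(0, 14) to |charge| < 10⁻⁴. Net charge is strictly decreasing in pH and
changes sign on that interval for every peptide (free termini), so the
root always exists. Our implementation agrees with Biopython's within
0.01 pH wherever Biopython's search window [4.05, 12] contains the root;
outside that window ours keeps bisecting and Biopython clamps.

## Motif scanning

Motifs are PROSITE-style bracket-class patterns (literal residues and
`[..]` alternative classes, one residue per position). Scanning reports
every overlapping occurrence (regex lookahead) with 0-based offsets.
Evaluation counts at the **peptide level**: a peptide is motif-positive if
any pattern matches anywhere; over a positive and a negative set,
PPV = TP/(TP+FP) and % coverage = 100·TP/(TP+FN). Per-motif tallies report
both distinct peptides hit and total occurrences, since "number of motifs"
is ambiguous between the two. The nine QSP motifs recovered at the
E-value-1 tier ship as the default pattern set; motif *discovery* (MEME)
is out of scope, so the bundled expressions are inputs, not outputs.

## Compositional and positional analyses

* `composition` pools residue counts across a set into percentages.
* `fold_change` compares a set against a background composition
  (a Swiss-Prot-style default ships, clearly marked approximate and
  normalized on load); enriched residues report query/background,
  depleted ones background/query, so every fold reads as a ratio ≥ 1 with
  a direction.
* `positional_enrichment` contrasts residue frequencies at the first and
  last k positions (C-terminal positions indexed negatively, −1 = last)
  between two sets with a two-sided two-proportion z-test with continuity
  correction at α = 0.05. A proportion test is the natural choice for
  per-position residue frequencies; no multiplicity correction is applied
  by default (matching common two-sample-logo practice) and a Bonferroni
  option covers the 20-residue × 2k-position family for conservative use.

## Design and mapping tools

`mutgen` enumerates all 19·L single-position mutants (position-major,
alphabetical); `qspepdesign` scores parent plus mutants and ranks by
decision value. `protfrag` produces ⌊(L−w)/step⌋+1 sliding windows;
`qspepmap` scores each window (default w = 12, the typical QSP length) and
merges touching or overlapping predicted-positive windows into candidate
regions. All machine-readable coordinates are 0-based and half-open.

## Synthetic data generator

The experimentally curated QSP corpus is not redistributable, so
`fixtures.generate` emulates its reported statistical structure:

* **Positives** (default n = 220): lengths lognormal(median 11.0,
  σ_log 0.45) clipped to [5, 30] (clipped mean ≈ 11.5–12); residue
  frequencies are the Swiss-Prot background re-weighted by the published
  QSP fold changes (C ×3.48, W ×3.11, F ×2.74, N ×1.79, Y ×1.51 enriched;
  E ÷2.68, H ÷2.20, D ÷1.74, V ÷1.54, R ÷1.48, K ÷1.24 depleted), which
  reproduces the reported mean aromaticity ≈ 0.18 without further tuning;
  terminal preferences multiply Ser ×3 at N-positions 1, 2, 3, 5, Gly ×2
  at 1–2, Phe ×2 at C-positions 1, 3, 5 and Cys ×2 at C-5 (multipliers
  chosen once so the aromatic total stays at its target).
* **Negatives** (default n = 220): lengths lognormal(median 28.5, σ_log
  0.50) clipped to [7, 77] (clipped mean ≈ 31.8), residues i.i.d. from the
  Swiss-Prot background (aromatic fraction ≈ 0.08).

Everything is deterministic given the seed. The generator reproduces the
*set-level* statistics the corpus is described by (lengths, composition,
aromaticity, molecular weight) but not its emergent biochemistry: the
synthetic sets' mean instability index and isoelectric point are whatever
i.i.d.-with-bias sampling yields (roughly 33–37 and 6.5–7.0 for both
classes), not the real sets' values, and no real motif, species structure
or phylogenetic redundancy is present. Classifier accuracies measured on
synthetic data therefore demonstrate that the pipeline extracts the
configured composition/length/terminal signal — on this emulation the
composition and hybrid models cross-validate in the high-80s/low-90s
percent — but they are not estimates of performance on curated biological
data.

`fixtures.make_separable` builds a deliberately easy control (positives
≥ 40% Trp, negatives Trp-free, length 15) for which any competent
composition-based classifier should approach 100% CV accuracy, with
label permutation collapsing it to chance; both ends are asserted in
tests.

## Numerical and design choices

* Residue order fixed alphabetical everywhere; encoders reject rather
  than impute non-standard residues (B, J, O, U, X, Z), because every
  downstream table indexes the 20-letter alphabet (strict parse mode
  errors; lenient mode drops the record with a warning).
* Duplicate removal is exact-sequence identity only, first occurrence
  kept; no similarity-based redundancy reduction.
* Train/validation splitting samples the per-class holdout uniformly
  without replacement from one global seed.
* AAC/DPC row sums hold to 1e-9; scramble-invariance of order-free
  features is exact up to float summation order (asserted at 1e-12).
* Problem sizes in the test suite and acceptance script (study-sized
  440-peptide sets, a 3×3 acceptance grid spanning the under-/over-fit
  regimes, coarse grids in unit tests) were chosen to keep full runs in
  the minutes range while preserving every qualitative contrast; the
  default 11×10 grid remains available everywhere.

## Known limitations

* Predicted secondary-structure fractions (helix/sheet/coil panels) are
  not computed: they would require an external structure predictor.
  AAindex secondary-structure propensity scales are the in-package proxy.
* The bundled Swiss-Prot background composition is a rounded snapshot;
  users comparing against a specific proteome should supply their own TSV.
* Cyclic or post-translationally modified quorum-sensing peptides are
  treated as their linearized sequences.
* PPV/coverage ladders across motif E-value tiers depend on motif
  discovery runs and cannot be recomputed from the bundled expressions.
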
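# Methods

## Problem and approach

Predicting whether two proteins interact is hard for any single
computational signal: phylogenetic co-occurrence works well in prokaryotes
but degrades in eukaryotes, and Gene-Ontology overlap captures functional
association rather than physical contact. `ppcm` treats every available
single predictor as a *base classifier* and stacks them: the per-pair scores
of the whole classifier grid become the feature vector of a Random-Forests
meta-classifier that emits the final interaction probability. The package
implements the full protocol — gold-standard construction, both base
classifier families, grid execution, stacking, and repeated ROC/AUC
evaluation — plus a synthetic multi-species benchmark so everything runs
end-to-end with no external downloads.

## Gold standard

Positives are curated interacting pairs (two-column TSV or a minimal PSI-MI
TAB subset; duplicates and self-pairs are dropped with a logged count).
Pairs are undirected: both orientations map to one canonical
lexicographically ordered pair. Reliable non-interacting pairs are scarce,
so negatives are drawn by randomly pairing proteins from a universe
(defaulting to the proteins of the positive set) and rejecting anything
positive, at an exact 1:r ratio. The conventional ratio is 1:100; AUC is
insensitive to the ratio (see the imbalance-robustness test), so the
synthetic benchmark uses 1:10 to keep repeated runs fast. Negative sampling
is rejection sampling with a dedupe set, switching to full enumeration and
choice-without-replacement when the request exceeds half the remaining
capacity, so it terminates even in dense regimes.

Repeated evaluation uses a stratified shuffle split (default train fraction
0.7), with the per-class training count rounded to the nearest integer, so
the class ratio is preserved up to rounding. Per-repeat seeds derive from
`SeedSequence(base_seed, repeat_index)`; repeats differ but the whole
protocol is reproducible bit-for-bit.

## Phylogenetic-profile classifiers

A profile is a binary presence/absence vector over a reference-taxa panel.
Three scorers compare the two rows of a pair over the selected taxa:

* **pp** — normalised Hamming similarity `1 − d_H/n`, in [0, 1]; the plain
  co-occurrence reading of profile comparison. Pearson and Jaccard variants
  exist conceptually but the grid uses the Hamming form.
* **mi** — plug-in mutual information of the two binary rows in bits
  (`0·log 0 ≡ 0`). Note the plug-in estimator is biased upward at small
  taxa counts; scores are used for ranking only.
* **hg** — upper-tail hypergeometric probability of observing at least the
  seen co-occurrence count given the two row sums, reported as `−log10 p`
  so larger means more interaction-like; `k = 0` maps exactly to 0 since
  `P(X ≥ 0) = 1`. p-values are floored at 1e−300 before the log.

Because profile informativeness depends on which taxa are compared, eight
reference-taxa optimisation strategies are registered: `identity` (all
taxa), `random_subset` (fraction 0.5), `redundancy_filter` (drop columns
with |Pearson r| ≥ 0.95 against an already-kept column; identical constant
columns count as duplicates), `tree_level_filter` (average-linkage
clustering of taxa at correlation distance, one medoid per cluster, 8
clusters by default), `greedy_forward` (iterative taxon selection maximising
the training AUC of the pp score, up to 10 taxa, returned in pick order),
`greedy_backward`, `genetic_algorithm` (bit-mask GA, population 16, 10
generations, tournament selection, elitism), and `simulated_annealing`
(150 Metropolis steps, linear temperature decay from 0.05). The supervised
strategies share one fitness function: the Mann–Whitney AUC of the mean
per-taxon agreement over the candidate subset, computed on the labelled
training pairs only — never on held-out pairs. These eight are this
package's own documented strategies; they fill the eight registry slots of
the grid rather than reproducing any particular third-party tool's
internals.

Cross-species classifiers calibrate (select taxa) on a source species'
network and then score target-species pairs with the target's profile rows
restricted to the selected taxa; this requires, and the synthetic generator
provides, a shared taxa panel across species.

## GO-annotation classifiers

Annotations are read from GAF 2.x (columns 2, 5, 9) or a protein/term/aspect
TSV. Semantic-similarity machinery over the GO DAG is deliberately out of
scope; instead a fixed set-overlap feature vector is computed per aspect in
the combo (BP, CC, MF and their four combinations): shared-term count,
Jaccard index, union size, overlap ratio (shared / smaller set), plus one
missing flag per aspect (features zeroed when either protein lacks terms in
that aspect). The features are symmetric in pair order by construction.

Two learners are registered: Gaussian Naive Bayes and a Random Forest
(√p features per split, seeded; 500 trees as the library default). A
learner trained on species-s pairs with species-s annotations transfers to
target pairs through the identical feature definitions — GO terms are a
shared vocabulary, so no orthology mapping is needed or attempted.

**Leakage control.** When scored pairs overlap a learner's own training
set (always the case for target-network classifiers), those pairs receive
out-of-fold scores from a 5-fold stratified CV (fold count reduced to the
minority-class size when necessary); all other pairs are scored by the
model fit on the full training set. The fold bookkeeping is exposed and
tested: each sample's score comes from a fold that excluded it.

## The grid and the meta-learner

The grid is a fixed cross-product: profile family = 3 methods × 8 taxa
strategies × 4 networks (EC, SC, DM, AT) = 96; GO family = 2 learners × 7
aspect combos × 7 networks (HS, MM, SP, SC, AT, EC, DM) = 98; 194 total.
Enumeration order (family, method, option, network, each in registry order)
and the canonical id `family|method|option|network` fix the score-table
columns. Category filters slice by training network: SC (14 GO / 24
profile), cross species (84 / 72), all.

`build_score_table` executes the grid over a pair list. Classifiers
sharing calibration work are grouped — one taxa selection per (strategy,
network) serves the three profile scorers; one feature matrix per (combo,
network) serves both learners. Pairs that cannot be scored by a profile
classifier (protein absent from the matrix) are imputed 0 — the "no
evidence" point of all three scorers — with a mask bit set. Per-classifier
seeds are derived by hashing the classifier id together with the run seed,
so scores do not depend on column order or on which other classifiers run.

The meta-learner is a Random Forest over the score columns of the variant's
category × subcategory slice (√p features per split, out-of-bag scoring
enabled when the forest and sample are large enough). Nine variants
materialise the 3 × 3 design. Models persist to a versioned pickle archive.

## Evaluation

ROC points are built by sweeping the distinct score values in descending
order; all pairs tied at a score advance in one step, so ties produce a
diagonal segment. AUC is the trapezoid sum
`½ Σ (X_k − X_{k−1})(Y_k + Y_{k−1})`, which with this tie handling equals
the Mann–Whitney statistic with ties counted ½ (asserted against a
brute-force pair-ordering oracle and an independent library
implementation). The protocol repeats the full split → score → stack →
evaluate cycle (25 repeats by convention) and reports mean ± SD per
classifier and per variant. The comparison report gives the mean over
single classifiers, the best single classifier, the ensemble mean ± SD,
the percent improvement over the best single (rounded to integer percent),
and a Welch two-sample t-test on the per-repeat AUCs (repeats treated as
independent samples; Welch because repeat counts or variances may differ;
degenerate zero-variance inputs short-circuit to p = 1 or 0).

Two repeat designs are provided. `run_evaluation` follows the benchmark
protocol: one fixed gold standard, repeats differing only in the split —
the right design for comparing methods on a given dataset, but its SD
reflects split noise only, because split-only repeats re-score subsets of
the same pairs and are not independent samples. `run_independent_replicates`
regenerates the synthetic dataset from a fresh seed every repeat, making
per-repeat AUCs i.i.d.; this is the design used for calibration questions
(e.g. verifying that, with no planted signal, every classifier's mean AUC
lies within 3 standard errors of 0.5 — on a fixed dataset that statement
is false in principle, since the dataset's own chance-level AUC deviates
from 0.5 by sampling noise that split repeats cannot average away).

## Synthetic benchmark

The generator plants interaction signal in two independent channels:

* **profiles** — rows are i.i.d. Bernoulli(0.5); for an interacting pair
  the partner's row is re-drawn to agree per taxon with probability
  `bg + s·(1 − bg)`, where `bg = q² + (1−q)²` is the agreement of two
  independent rows and `s` is `coevolution_strength`. Each protein's row is
  planted at most once, so chains of overlapping positives stay consistent
  (a few positives in dense neighbourhoods remain at background — visible
  as a low tail in the positive score distribution, as in real data where
  not every interacting pair co-evolves).
* **GO** — background: each term enters a protein's annotation with
  probability 0.05; for an interacting pair each term is additionally
  co-assigned to both partners with probability
  `go_sharing_strength × 0.05`.

Default conditions: 7 species (disjoint protein spaces, shared taxa panel
and GO vocabulary), 300 proteins and 50 interacting pairs per species, 40
taxa, 60 terms per aspect, negatives at 1:10. Strengths default to
coevolution 0.25 and GO sharing 0.5, chosen so the two families' single
classifiers land in distinct mid-range AUC bands (profiles roughly 0.6–0.8,
GO roughly 0.8–0.95 at desk scale) — strong enough to rank, far from
saturation, and split across channels so no single family carries all the
signal. With both strengths at zero the generator is an exact null and
every classifier's mean AUC is statistically indistinguishable from 0.5.

What the generator does **not** emulate: GO DAG structure (terms are a flat
vocabulary, so depth-aware semantic similarity would add nothing here),
phylogenetic correlation between taxa columns, degree-heterogeneous
interaction networks, orthology relationships between species, and
annotation incompleteness bias. Passing tests therefore demonstrate that
the pipeline's machinery — leakage-free stacking, calibration transfer,
evaluation — behaves correctly under controlled signal, not that any
particular AUC level will be attained on real curated data.

## Numerical and design choices

* Pair canonicalisation is lexicographic; label is excluded from pair
  identity so positive/negative sets compare as plain sets.
* The negative-to-positive ratio is authoritative; dataset size follows
  from it rather than from any absolute target.
* Score-table determinism: same seed ⇒ byte-identical TSV serialisation.
* Greedy/GA/annealing tie-breaks go to the lowest column index (first
  argmax); supervised selections are therefore deterministic given seed.
* Repeated-evaluation tree counts default to 100 (base learners) and 200
  (meta-forest) so a full 194-classifier × 25-repeat protocol completes in
  minutes on one core; the learners' own API default remains 500 trees.
* Supervised taxa selection maximises *training* AUC and is not itself
  cross-validated; its training columns are optimistically biased, which
  the meta-forest sees and partially discounts. This mirrors the cost any
  wrapper-style feature optimisation pays and is documented rather than
  hidden.

## Known limitations

* The profile-family ensemble can trail its best single classifier on the
  synthetic benchmark (selection-overfit training columns, few positives
  per split); the combined ensemble is the quantity with the dominance
  guarantee and is what the acceptance suite checks.
* Plug-in MI is biased for small taxa subsets; rankings are still valid.
* The grid's eight taxa-strategy slots and the GO feature set are this
  package's own definitions; counts and structure match the published grid,
  member-by-member behaviour of the original tools is not claimed.
* Real-data headline AUCs from curated interaction databases are out of
  scope; nothing in the tests asserts them.
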
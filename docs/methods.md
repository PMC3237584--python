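# Methods

## Structure standardization ("washing")

Every input structure is reduced to a canonical, comparable form before
any descriptor is computed: the largest connected fragment is kept (ties
broken by heavy-atom count, then lexicographic canonical-SMILES order, so
the choice is deterministic), counter-ions disappear with the discarded
fragments, charges are neutralized by protonation/deprotonation of common
ionizable groups (permanently charged centres such as quaternary nitrogen
keep their charge — neutralizing them would break valence), stereochemistry
is removed, explicit hydrogens are stripped, and the result is written as
canonical SMILES. Stereochemistry is dropped deliberately: every
downstream representation here is 2-D and stereo-blind, and removing it
makes deduplication by canonical string reliable. Washing is idempotent;
the test suite asserts `wash(wash(m)) == wash(m)`.

Curation filters run in a fixed order with conservation bookkeeping
(input = retained + Σ removed, per stage): molecular weight ≤ 1000 Da
(the boundary is inclusive — "maximum" names the largest admissible
value), then total atom count including implicit hydrogens ≥ 3, then
removal of metabolite-set entries whose taxonomy annotation fields match
a drug pattern (case-insensitive substring; fields and patterns are
configurable because annotation vocabularies vary across database
versions), then removal from the background set of any structure whose
canonical SMILES occurs in the metabolite set.

## Descriptor sets

| name | contents |
|---|---|
| `atom_counts` | H, C, N, O, F, P, S, Cl counts (8 entries) |
| `pp_desc` | atom counts + MW, total atoms, logP, logD, H-donors/acceptors, rotatable bonds, rings, aromatic rings, log-solubility, TPSA, minimized energy (20 entries) |
| `ecfp4` | circular fingerprint, diameter 4, atom-type identifiers, folded to 1024 bits |
| `fcfp4` | as above with pharmacophoric functional-class identifiers |
| `mdl_keys` | the 166 public structural keys |

Open estimators stand behind the continuous properties: Crippen
atom-contribution logP; logD at pH 7.4 approximated as logP minus a fixed
ionization penalty (−3.0 when an acidic group — carboxylic, sulfonic, or
phosphoric — is present, otherwise −2.0 for a basic aliphatic
amine/amidine; a deliberately coarse rule, since only the descriptor's
rank information matters to the classifiers); Delaney-style ESOL log
aqueous solubility; topological polar surface area. `Minimized_Energy`
defaults to a 0.0 sentinel because single-conformer energies are
expensive and noisy; an optional MMFF94 path (embed, minimize, report
kcal/mol) can be enabled. These values are not expected to match any
proprietary calculator bit-for-bit; what matters downstream is the
descriptor-set membership and discriminative content.

"ECFP_4" follows the universal diameter convention: neighborhood radius
2, i.e. identifiers for rounds 0..2, duplicate environments removed.
Folding maps each sparse identifier to `id mod 1024` and ORs collisions;
bit-packing order is an output-serialization detail with no effect on
presence/absence features. The structural keys use the openly published
166-key SMARTS set; individual keys may differ from vendor dialects, which
is accepted and does not affect the pipeline's structure.

## Diversity selection

Tanimoto similarity |A∩B|/|A∪B| over folded ECFP_4 bits (defined as 1.0
for two all-zero fingerprints, which denote identical empty feature
sets); dissimilarity = 1 − Tanimoto. The maximal-dissimilarity partition
is greedy MaxMin: the first center is the first molecule in
canonical-SMILES sort order (the reference tool's start point is
undocumented; sorting makes the partition reproducible), each subsequent
center is the molecule whose minimum dissimilarity to the current centers
is largest, and selection stops when that value falls to ≤ 0.6. Every
molecule is then assigned to its nearest center, ties to the
earlier-selected center. Two invariants hold by construction and are
audited exhaustively in tests: member-to-center dissimilarity ≤ 0.6, and
center-to-center dissimilarity > 0.6.

Training sets are balanced: all metabolite centers plus an equal-size
seeded uniform draw from the background pool; the test set takes the
non-representative metabolites and the unused background molecules,
downsampling the majority class (seeded) to balance.

## Classifiers and tuning

* **Random Forest** — 500 trees (the conventional default), `mtry`
  features sampled per split, bootstrap aggregation. The
  metabolite-likeness score is the fraction of trees voting metabolite
  (trees are grown to purity, so averaged leaf probabilities equal vote
  fractions). A degenerate test configuration (1 tree, all features, no
  bootstrap) reproduces a single decision tree.
* **RBF-SVM** — maximum-margin fit with Gaussian kernel; scores come from
  a Platt sigmoid 1/(1+exp(Af+B)) fitted on the training decision values
  with the standard smoothed targets.
* **Naïve Bayes** — written from scratch. Binary descriptors: per-bit
  Bernoulli likelihoods with additive smoothing 1 (Laplace); continuous
  descriptors: per-class Gaussian likelihoods with a variance floor;
  prior ½ for balanced data. On ≤ 4-bit problems the posterior matches a
  hand-enumerated Bayes computation exactly (tested).

Metaparameters are tuned by stratified 5-fold cross-validation (per-class
fold sizes differ by at most 1): the selected point maximizes mean
held-out AUC, ties broken by smaller mean classification error, then by
smaller parameter values. Grids: `mtry` ∈ {⌊√p⌋/2, ⌊√p⌋, 2⌊√p⌋, p/4};
γ ∈ 2^{−15..3} and C ∈ 2^{−5..15}, log-spaced with step 4 (a coarser
2-point/4-point "small" grid drives the fixture pipeline). A molecule is
called a metabolite when its score ≥ 0.5; the boundary is inclusive and
the cutoff configurable.

## Evaluation

Sensitivity = 100·tp/(tp+fn), specificity = 100·tn/(tn+fp); undefined
ratios are reported as missing, never as 0. AUC is the Mann–Whitney
statistic computed from midranks (ties ½), which equals the trapezoidal
area under the threshold-swept ROC curve; a brute-force pair-counting
oracle verifies both on random instances. The benchmark table holds one
tuned model per descriptor × classifier cell with row (per-descriptor)
and column (per-classifier) averages computed from unrounded cells;
`from_rounded=True` averages the 2-decimal printed values instead, for
cross-checking published tables that did the same. Percent values are
rounded half-away-from-zero to 2 decimals at report time only. Score
distributions are binned into ten width-0.1 bins on [0, 1], the last bin
closed.

## Chemical-space analysis

PCA standardizes each column to unit variance (constant columns are
dropped with a warning — the energy sentinel is constant by design) and
eigendecomposes via SVD; the sign convention makes each component's
largest-magnitude loading positive, so results are deterministic.
Clustering runs on the PCA scores — by default the leading components
covering ≥ 95% of variance, configurable since there is no canonical
choice — with Ward's minimum-variance linkage on Euclidean distances.
The dendrogram is cut at the point of maximal loss of intra-cluster
inertia: with Ward linkage the inertia gained by the merge taking k
clusters to k−1 equals height²/2, so the chosen k ∈ [2, 10] maximizes
ΔW(k)/ΔW(k+1). On three well-separated planted blobs this recovers k = 3
for every seed tested. Cluster purity is 100 × dominant-class count /
cluster total.

The conditional inference tree works on binary (presence/absence)
features, by default unhashed ECFP_4 identifiers occurring in ≥ 5
molecules (rarer features produce degenerate tests). At each node the
two-sided exact association p-value of every candidate feature with the
class label is computed from the hypergeometric distribution — the
permutation distribution of a 2×2 count statistic is hypergeometric, so
this equals exhaustive permutation enumeration, verified at n = 6 —
Bonferroni-adjusted over the features tested at that node. The node
splits on the minimum adjusted p-value when it is ≤ α = 0.05 and the node
holds ≥ 20 samples, feature-present samples going left. Child counts sum
to parent counts at every node, and the null split rate stays within
binomial tolerance of α (both tested).

## Fragment analysis

Five kinds per molecule, deduplicated within a molecule and reported as
plain canonical SMILES without attachment points: each smallest **ring**;
each maximal fused **ring assembly** (rings sharing an atom, covering
fused and spiro junctions); each **bridge assembly** (two ring assemblies
plus the shortest simple linker joining them, skipped when the path runs
through a third assembly); each **chain** (connected component of
non-ring heavy atoms); and the **Murcko** scaffold (ring systems plus
linkers, side chains pruned — idempotent by construction). Ring-bearing
fragments are extracted aromatic-first, falling back to a kekulized copy
when an aromatic fragment cannot stand alone. The reference tool's exact
category semantics are unpublished; these definitions are fixed here and
fixture-tested (toluene, naphthalene, biphenyl, bibenzyl). Frequency
tables use per-molecule presence (multiplicity ignored), exclude
fragments with < 4 heavy atoms, and rank by frequency in the focal set,
ties by canonical SMILES.

## Synthetic data and what it can show

`gen_bernoulli_fingerprints` draws each bit independently per class with
exact class counts. Defaults: 64 bits, 24 informative (p₁ = 0.62 vs
p₀ = 0.38), 40 uninformative at 0.5, 500 molecules per class — a moderate
feature-frequency contrast with a majority of uninformative bits, the
situation folded fingerprints of metabolites versus screening compounds
actually present. Class-conditional independence is exactly the NB
assumption, so NB is Bayes-consistent for this generator and the exact
log-likelihood-ratio score is Bayes-optimal. `analytic_bayes_auc`
computes that score's AUC by exact convolution of the per-bit LLR
distributions for ≤ 20 bits (values rounded to 10 decimals to merge equal
sums; zero-probability branches skipped so deterministic bits behave as
point masses) and by seeded Monte Carlo (10⁶ draws) otherwise; a
brute-force enumeration over all 2³ outcomes verifies the 3-bit case.
Trained RF and NB models recover this AUC to within ±0.03 at 500+500.

The toy molecule fixture packs ~90–100 deterministic structures per
class: sugars, polyols, hydroxy/keto/amino acids, phosphates, nucleosides
and sterols on the metabolite-like side; anilines, secondary amines,
pyridines, piperazines, azoles, thiophenes, thiazoles and thioethers on
the synthetic-like side. The synthetic-like set contains no oxygen at
all, so the tree's root split and the top metabolite fragment (an oxygen
heterocycle — the pyranose ring is the largest shared ring system) are
predictable by construction. What passing fixture tests show is that the
machinery is wired correctly end to end; they do not show field
performance on real databases, where the class contrast is far subtler,
classes overlap, and annotation noise exists. Likewise the synthetic
generator omits bit correlations (an optional stress mode exists in the
analysis code path via custom probability vectors) and any notion of
chemical validity.

## Problem sizes and numerical choices

The fixture pipeline trains on 2 × 19 diversity centers and tests on
72 + 72 held-out molecules, with the coarse CV grids; it completes all 15
benchmark cells in well under five minutes on one CPU and is
bit-reproducible for a fixed config (every stochastic stage derives its
seed from the config seed). Parameter-recovery checks use 500 + 500
training and test fingerprints. Ties are broken deterministically
everywhere (canonical-SMILES order in diversity selection, earlier center
on assignment, lowest feature index in the tree, smaller parameters in
CV); degenerate inputs (empty files, single-class labels, all-zero
fingerprints, constant columns, odd fingerprint diameters, out-of-range
scores) raise errors or documented conventions rather than propagating
silently.

## Known limitations

* The score is only as good as the curated class contrast; with the
  packaged fixture it demonstrates mechanics, not chemistry-wide
  validity.
* logD and solubility estimators are intentionally simple; rank
  information, not absolute values, is what the models consume.
* Bridge-assembly semantics follow this package's definition; other
  tools' categories with the same name may differ.
* The conditional inference tree tests only 2×2 associations (binary
  features, binary response) — continuous covariates are out of scope.
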
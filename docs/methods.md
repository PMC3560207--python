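# Methods

This note documents the models and procedures implemented in `mircircuit`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Study design and data model

The design is three MCF7-derived cell lines — the parental drug-sensitive
line (`parent`) and two antiestrogen-resistant sublines (`T`, tamoxifen;
`F`, fulvestrant) — each profiled in duplicate on a miRNA and an mRNA
microarray: six samples per matrix, columns named `<line>.<replicate>`.
Two contrasts are hard-wired as `T_vs_P` and `F_vs_P` (subline over
parent); a positive log2 fold change always means higher expression in the
resistant subline.

`ExpressionMatrix` carries linear intensities (strictly positive) or log2
values with an explicit scale flag; all statistics are computed on log2
scale.

## Normalization and fold changes

Quantile normalization maps every column onto the vector of per-rank
cross-column means. Tied values within a column receive the mean of the
rank-means over their tied rank range — the standard convention, which
makes the operation deterministic and idempotent. Note the consequence: a
column containing ties does not carry the exactly identical multiset
afterwards (tied entries collapse onto their group mean); on continuous
intensity data ties have probability zero.

Fold change is the difference of replicate means on log2 scale (not the
ratio of linear means): symmetric in up/down regulation and consistent with
log2-processed array data. Other summaries (medians, ratios of linear
means) are defensible; the mean-of-log2 choice is this package's own.

The inverse-expression call `is_inverse` is sign-based: miRNA and target
log2 fold changes must have strictly opposite signs and both magnitudes
must reach `min_abs_log2fc` (default 0, i.e. a pure sign condition; an
exactly zero fold change never passes). A circuit is retained when the
condition holds in *at least one* of the two contrasts, with per-contrast
flags preserved — the same topology is then displayed per contrast, which
is how differential network usage between the two resistant states becomes
visible. Regulator → miRNA edges are never expression-filtered; the inverse
condition concerns only miRNAs and their targets.

## Knowledge base and circuit assembly

The regulator table (TransmiR-style: regulator gene, role ∈ {TF,
signaling}, direction ∈ {activation, repression, unknown}, miRNA) and the
target table (miRTarBase-style: miRNA, target gene, evidence tag) are read
from TSV with fixed column names and free column order; duplicate rows
collapse (topology, not evidence counting, drives all downstream
statistics). Gene identifiers are resolved against a foreign-ID → symbol
map; records that resolve neither directly nor as existing symbols are
returned separately, never silently dropped. miRNA names are canonicalized
(`miR-221` → `hsa-mir-221`; arm suffixes preserved), and the two tables
join only on exact canonical equality — a lenient stem join would silently
merge distinct arms.

Circuit assembly is the exact triple join {(r, m, t) : r→m in the regulator
table, m→t in the target table, t ∈ TF/signaling universe}. The universe is
the set of regulator-table genes plus an optional user-supplied annotation
list; no canonical list of "TF- and signaling-protein-encoding genes"
accompanies the source databases, so the regulators themselves, optionally
extended, are the only principled universe available.

## Context mining

Eight cancer hallmarks are represented by nine MeSH terms (mutation;
cyclin dependent kinase inhibitor proteins; cell death; receptors cytokine;
drug resistance neoplasm; angiogenesis inducing agents; glycolysis;
epithelial-mesenchymal transition; genomic instability). Immunosuppression
is deliberately not inspected: the in vitro cultures contain no immune
cells. The pairing of hallmark labels to terms is this package's own
reasonable assignment; the enforced invariant is the term list itself.

Association edges come from exact per-document membership counts over a
local JSON-lines corpus: for gene g and term t,
`p = P(X ≥ n_both)` with X hypergeometric (population `n_total`, successes
`n_gene`, draws `n_term`). An edge is emitted when `n_both ≥ min_count`
(default 1) and `p ≤ max_p` (default 0.05). A live co-citation service
publishes no inclusion criterion, so an explicit over-representation test
with visible knobs is used instead; Benjamini–Hochberg correction across
all tested pairs is available behind a flag and off by default. A gene or
term absent from the corpus yields n_both = 0 and p = 1 — an outcome, not
an error.

## Network statistic and permutation test

Every inhibition (miRNA→target) and regulation (regulator→miRNA) edge is
scored `s·r`, where r is the Pearson correlation of the endpoints' log2
profiles across the six samples and s is the expected sign: −1 for
inhibition and repressive regulation, +1 for activating or
unknown-direction regulation. Without the sign weighting, coherent
activation and coherent inhibition would cancel in the mean. Association
edges carry no expression hypothesis and are excluded. Pearson is the
default (Spearman behind a flag); with six samples a rank correlation has
little resolution, and the generative model for the synthetic data is
linear-Gaussian on log2 scale. Zero-variance profiles make an edge's score
undefined; such edges are excluded from the mean and counted.

The null model permutes the assignment of profiles to node labels *within
feature class* — miRNA profiles among miRNA nodes, gene profiles among gene
nodes — keeping topology fixed. Cross-class swaps would break
exchangeability: the two classes come from different array platforms with
different value distributions. The one-sided upper-tail p is reported two
ways: raw (`k/n_perm`, which legitimately prints `0.000` at three decimals
when no permutation reaches the observed statistic — the conventional way
such results are reported) and add-one corrected (`(k+1)/(n_perm+1)`),
which can never be exactly zero and is the value used in all assertions
here, since p = 0 is impossible under a valid permutation null. Default
`n_perm` = 5000.

The permutation kernel is vectorized: profiles are centered and
unit-normalized once, so each edge score is a dot product, and all
permutations are evaluated as one batched einsum.

### Calibration and power, and one subtlety

The test suite checks type-I calibration on datasets with *no planted
coherence*: the fraction of corrected p ≤ 0.05 over 200 independent null
datasets must lie near the nominal level. Calibration is measured on the
planted topology *without* inverse-expression refinement. This is
deliberate: refinement selects edges by opposite fold-change signs, a
quantity correlated with the edge-score statistic, so a network selected by
refinement is enriched for high-scoring edges *by construction* and the
permutation p on it answers "is this selected network more coherent than a
random labeling" — a different, selection-biased question. The exact
exchangeable null for the test itself is the unrefined topology, and that
is what the calibration study uses. Power is checked on planted coherence
(anti-correlation 0.9, noise SD 0.3, 27 coherent inhibition edges):
corrected p ≤ 0.01 in ≥ 95/100 datasets at 1000 permutations.

## Markov clustering and selection

MCL treats the network as undirected, unit-weight, with self-loops added:
column-stochastic normalization, then repeated expansion (matrix power,
default 2), inflation (entrywise power 2.0, renormalize) and pruning of
entries below 1e−5, until the largest entrywise change drops below 1e−8 or
200 iterations pass (the latter returns the current clustering flagged as
non-converged). Clusters are read off attractor rows (nonzero diagonal); a
node with several attractors joins the lowest-indexed one, which resolves
overlapping attractor systems deterministically. Context nodes participate
in clustering — association edges are real edges, and the reference
figures' clusters visibly contain context terms. Edge weights are uniform
because the source tables are binary evidence.

Selection keeps clusters of size ≥ 2 ("non-orphan"), then the top 10
largest with at least five elements, ties broken by the lexicographically
smallest member — the selection convention used with Cytoscape's
clusterMaker plug-in in analyses of this kind. clusterMaker bundles several
algorithms without a single canonical default; MCL is its canonical
network-clustering option and is fully specifiable, which is why this
package implements MCL rather than wrapping the plug-in.

`recovery_score` (mean over truth clusters of the best Jaccard index
against any found cluster) quantifies planted-structure recovery. On random
3-module graphs (intra-module density 0.85, inter 0.03) MCL at defaults
recovers ≥ 0.8. On the synthetic *pipeline* network the score is lower
(~0.6–0.7): each planted module is a layered bipartite chain (regulators —
miRNAs — targets — context terms), and MCL tends to cut long chains into
two clusters. This is a property of MCL on that topology, reported as
computed, not tuned away.

## The synthetic-data generator

What it emulates: the 3-line × 2-replicate array design; log2-normal
intensities (baseline Uniform(6, 12) per feature, Gaussian noise, then
exponentiated to linear scale); planted fold changes of ±`effect_size`
(miRNA down, target up in the affected subline); tunable miRNA–target
anti-correlation via a shared latent per-sample factor loaded −1 on miRNAs
and +1 on targets, scaled so the expected Pearson r is
−`anticorrelation_strength` (one factor per connected component of the
planted pairing); evidence tables with planted circuits plus three decoy
categories (regulators of array-absent miRNAs, targets outside the
TF/signaling universe, and planted rows rewritten under RefSeq-style
foreign IDs so the identifier-mapping step is load-bearing); and a document
corpus with independent gene/term inclusion plus co-injected planted pairs
(independence gives an exact null for the hypergeometric test).

Defaults: 30 miRNAs, 60 mRNAs, noise SD 0.3 (log2), effect size 1.0 (a
two-fold change — a conventional array effect worth detecting),
anti-correlation 0.8, three modules of 2 regulators × 3 miRNAs × 3 targets
(54 circuits, 27 distinct miRNA–target pairs), 200 documents with gene
inclusion 0.03 and term inclusion 0.08 and 10 co-injected documents per
planted association — sparse enough that chance co-occurrence stays low
and a planted pair's p beats every decoy pair in 98 of 100 seeded corpora.

What it does not emulate: probe-level array artifacts, background
correction, batch effects, sequence-level target matching, correlated decoy
structure, or literature synonymy. Passing tests therefore demonstrate the
*pipeline's* correctness and statistical behavior under a clean generative
model, not robustness to real-array noise sources.

One interaction is worth knowing about: the generator plants 9 of 30
miRNAs (and 9 of 60 mRNAs) as differentially expressed, which mildly
violates quantile normalization's working assumption that most features
are unchanged between samples. On such a small, signal-dense matrix,
normalization shrinks some planted miRNA fold changes toward zero, so the
end-to-end inverse-expression recall is seed-dependent (typically 0.89-1.0
of planted circuits; precision is always 1.0 because decoys cannot
assemble). Real arrays, with thousands of features and a small
differential fraction, sit much closer to the normalizer's assumption.

Determinism: one global seed drives every stage through keyed SHA-256
splitting (`child_seed(seed, key)` < 2^31), so identical (config, truth,
seed) reproduce bit-identical outputs, and changing one stage's consumption
(e.g. `n_perm`) never perturbs another stage's stream.

## Degenerate inputs and numerical choices

Single-column matrices cannot be quantile-normalized (rejected); missing
cell lines, contrast mismatches, unknown evidence-table columns and unknown
export formats are rejected with the offending name; circuits referencing
features without fold-change rows are dropped and counted; association
edges naming genes absent from all circuits are dropped and counted; an
all-association network has no scorable edges and is rejected by the
permutation test. Fold-change color mapping interpolates linearly in log2
space separately on each side of the neutral anchor at ratio 1 (so the
anchor is exact even on asymmetric ranges such as 0.039–12.4) and clips
beyond the extremes; the scale must straddle ratio 1. Idempotence of
quantile normalization is exact up to one floating rounding of a
mean-of-identical-values (asserted at 1e−9).

## Known limitations

* Results obtained on real arrays with specific miRTarBase/TransmiR
  releases (exact cluster counts and memberships, the permutation p of a
  real network, fold-change color extremes) depend on those inputs and are
  not reproducible from synthetic data; the package validates properties of
  the method, not any particular dataset's numbers.
* With two replicates per line, per-feature fold changes are noisy; the
  sign-only inverse condition is intentionally permissive, and a magnitude
  threshold is available but defaults to 0.
* Six samples bound the resolution of any per-edge correlation; the network
  mean and its permutation null, not individual edge scores, are the
  meaningful quantities.
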
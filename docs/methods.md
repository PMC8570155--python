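# Methods

`genesharenet` analyses the gene contents of giant-virus (NCLDV) genomes
through orthogroup presence/absence rather than through sequence
alignment.  Its inputs are the outputs of an upstream ortholog-clustering
run (an OrthoMCL-style groups file), a genome metadata table and,
optionally, a core-gene tree.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## The sharing statistic

For taxa *i*, *j* (genomes, or family pangenomes obtained by pooling all
genes of a family's genomes), let U_ij be the number of orthogroups
present in both, and T_i the number of orthogroups of *i* present in at
least one *other* taxon of the matrix under analysis.  The sharing level
is

    S_ij = U_ij / sqrt(T_i * T_j)

The geometric mean keeps a gene-rich partner (a mimivirus next to a
poxvirus, say) from dominating the normalization.  Properties relied on
downstream, all covered by tests against brute-force set enumeration:

- 0 ≤ S ≤ 1, symmetric; S = 1 exactly when the two shared repertoires
  are identical and fully mutual; S = 0 for disjoint repertoires.
- Orthogroups private to one taxon are invisible: they enter neither U
  nor T, so sampling more strain-specific genes never dilutes S.
- T is computed over the taxon set of the matrix at hand, so genome-level
  and pangenome-level S values are normalized within their own context
  and are not comparable across contexts.
- An isolated taxon (T = 0) gets S = 0 by definition, never NaN.

Presence/absence drives U and T; gene copy numbers are retained in the
count matrix only for the copy-number summaries of the host screen.

## Markov clustering

The genome network (edge iff U ≥ 1, weight S) is clustered with a dense
from-scratch MCL: add self-loops at each node's maximum incident weight,
column-normalize, then alternate expansion (matrix square) and inflation
(entrywise power r followed by column renormalization), pruning entries
below 1e-5 and renormalizing, until the maximum entrywise change falls
below 1e-6 (cap 200 iterations; non-convergence is flagged, not fatal).
Clusters are read off the limit matrix: attractors are the nodes with
positive diagonal mass, attractor systems are the connected components
of the limit structure restricted to attractors, and every other node
joins the system receiving the largest share of its column mass (ties
resolved toward the system containing the lexicographically smallest
attractor).  Cluster labels are numbered by smallest member id, so the
output is invariant to node input order.

Inflation r is the granularity knob.  Two facts from the synthetic
benchmark are worth keeping in mind:

- On default synthetic datasets, r = 1.5 resolves the *family-pair*
  level of the planted hierarchy (the two families linked by a shared
  host-gene pool merge; ARI = 1 against the pair partition on 20/20
  seeds), while r = 2.0 resolves the planted families exactly (ARI = 1
  on 20/20 seeds).  Granularity selects a level of the hierarchy, and
  the level it selects depends on how much cross-cluster flow the data
  carries; with real data, where cross-family sharing is proportionally
  weaker, low inflation fragments along different lines.
- Cluster count is not strictly monotone in inflation; the suite treats
  monotonicity as a statistical property (≤ 5% violations tolerated).

## Intrafamilial variation and host diversity

Strain databases oversample popular lineages, so all family-level
variation is computed between lineages: per-genome values are averaged
within each lineage first.  Per family we report the sample SD (n−1; the
statistical default, documented because "standard deviation" alone is
ambiguous) of lineage-mean protein counts and of lineage-mean singleton
counts, and the mean between-lineage patristic distance on the core-gene
tree (all cross-lineage tip pairs averaged per lineage pair, then
averaged over lineage pairs; a `representative` mode using one genome
per lineage exists for sensitivity checks).  Families with fewer than
two lineages report missing values, and singleton SDs are missing —
never zero — when no protein index was supplied.

Host diversity is the Shannon index D = −Σ p_j ln p_j over the six
eukaryotic supergroups with known NCLDV hosts (Amoebozoa,
Archaeplastida, Discoba, Haptista, Opisthokonta, SAR), where p_j is the
fraction of the family's lineages assigned to supergroup j; 0 ≤ D ≤
ln 6 ≈ 1.792.  A lineage spanning several supergroups takes the
majority one; an exact tie is a hard error so the user decides.

## Host-association comparisons

For a family pair and a focal host type, every cross-family virus pair
is routed to "similar" (both infect the focal type) or "dissimilar"
(exactly one does); pairs touching the focal type in neither virus are
excluded.  A one-sided Mann–Whitney–Wilcoxon test asks whether similar
pairs share more.  The implementation uses midranks throughout; when
n₁·n₂ ≤ 400 the p value is exact, computed by a shift-algorithm dynamic
program over the (doubled) midranks — ties are thereby handled exactly —
and otherwise by the normal approximation with tie-corrected variance
and a 0.5 continuity correction.  The exact branch reproduces scipy's
exact MWW on tie-free data and a full permutation test on tied data.

One caveat carried into any interpretation: the all-pairs design reuses
each genome in many pairs, so the S values entering the test are
positively correlated and the nominal p value is anticonservative
(measured type-I error ≈ 11% at α = 0.05 on null synthetic data).  The
test itself is correctly calibrated where its independence assumption
holds: on a random disjoint matching of cross-family genomes the
measured null rejection rate is 4–5% at α = 0.05 (1,000 simulated null
datasets of 2 families × 3 lineages × 8 genomes — sizes chosen so the
exact permutation distribution is fine-grained enough to reject at all).
The calibration in the test suite and acceptance script uses that
matched design.

The orthogroup screen identifies gene families behind a host signal: an
orthogroup is shared-by-target if at least one target-host virus of
*each* family carries it; the report keeps orthogroups shared-by-target
and not shared-by-reference, with carrier frequencies averaged across
the two families, their difference (sort key, descending, ties by id),
and the mean copy number among target-host carriers averaged over the
families that have at least one carrier (a family with none is skipped,
not averaged in as zero).  Swapping target and reference provably yields
a disjoint report.

## Synthetic data

The generator plants exactly the structure the statistics are meant to
detect: 5 universal-core orthogroups in every genome; a 100-orthogroup
family-core pool retained per genome with probability 0.8; 20
lineage-private orthogroups per lineage; a 30-orthogroup host-type pool
retained with probability 0.7 by every genome of that host type across
families; Poisson(10) private singletons per genome; copy numbers
1 + Poisson(0.1) per present gene.  Families come in pairs splitting two
host types between alternating lineages (vertebrate/insect and
alga/amoeba), so each host type spans two families, as in the real
family pairs the comparative design targets.  The default layout is
4 families × 3 lineages × 4 genomes.  The host-pool size and retention,
and the 4×3×4 layout, define the standard recovery regime of the test
suite; the family-core pool size of 100 reflects the tens-to-hundreds of
core genes typical of an NCLDV family, and retention 0.8 mimics ongoing
gene loss.  Copy numbers use the simplest model that produces the
multi-copy families the screen's copy-number column summarizes; it is a
stand-in, not a biological claim.  A nested family > lineage > genome
tree accompanies the catalog, with exponential branch lengths (means
0.5 / 0.2 / 0.05 for family stems, lineage stems and tips) so patristic
structure separates the levels; it is not calibrated to real data.
Orthogroups left with a single member protein are demoted to singletons,
as an ortholog-clustering run would leave them unclustered.  One seed
drives everything; written files embed it in a header comment.

What the synthetic benchmark does not emulate: realistic repertoire
sizes (real genomes carry far more accessory genes, making cross-family
S proportionally smaller), lateral-transfer mechanisms, annotation
noise, or multi-host viruses.  Passing it demonstrates the statistics
and their implementation, not performance on any particular real
dataset.

## Problem sizes and determinism

The suite and the acceptance script run on the 48-genome default regime
(hundreds of orthogroups), 20-seed recovery sweeps, 100-seed power
checks and 500–1,000-dataset null calibrations; these sizes give stable
averages while keeping a full run in well under a minute of compute for
the pipeline stages.  All randomness flows from explicit seeds; the
pipeline writes a manifest of SHA-256 checksums and reruns are
byte-identical.

## Known limitations

- S values are context-dependent by construction; do not compare
  genome-level and pangenome-level values numerically.
- MCL granularity must be chosen for the question at hand; there is no
  universally correct inflation, and cluster counts on real data are
  sensitive to the self-loop and pruning policy.
- The all-pairs MWW p values are anticonservative (above); treat them
  as descriptive strength-of-signal summaries, not calibrated error
  rates.
- Lineages are taken from the metadata as given; the package does not
  infer them from the tree.
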
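# Methods

## Scope and model

`peptrace` analyses the four peptidase families that process and degrade
organelle targeting peptides (MPP, SPP, PreP — MEROPS M16; OOP — M3).
The workflow has five analysis stages — homolog cataloguing, gene-tree
construction, distance-to-eukaryote metrics, co-occurrence enrichment and
motif statistics — plus a synthetic-data generator that produces labelled
inputs with known event-level ground truth. The analysis code never reads
the ground truth; it is used only to score results in tests.

## Homolog cataloguing

A reference peptidase (by default a eukaryotic member of each family) is
searched against all proteomes with phmmer; hits need E ≤ 1e-5 and ≥ 70%
query coverage (coverage is measured on the reference, i.e. the fraction
of its positions inside the local alignment envelope). Hits are
partitioned by clade; clusters under 5 hits are merged into the nearest
sister clade on the clade tree (topological distance, ties alphabetical).
Each cluster becomes a profile HMM (longest member anchors a
single-sequence profile, members are aligned to it with hmmalign, and the
alignment is rebuilt into the final profile). The profiles re-scan the
proteomes; a protein is a candidate when for at least one profile
E ≤ 1e-2 and the alignment covers > 70% of that profile's match states.
Candidates are annotated with the motif models (E ≤ 1e-2, per-domain
independent E-value, same-motif overlaps resolved greedily by score) and
kept as homologs of a family only if their motif multiset contains the
family requirement — multiplicity-aware, so SPP needs two non-overlapping
M16C hits. A candidate satisfying several compositions is reported under
each, with the largest requirement flagged primary (ties alphabetical).
Additional domains beyond the requirement are catalogued at E ≤ 1e-5.

All searches run through pyhmmer with a single worker and the database
size Z pinned to the number of target sequences, which makes every
E-value deterministic and comparable between runs. Default thresholds
(1e-5 / 70% seed, 1e-2 / 70% scan, 1e-2 domains, 1e-5 extra domains,
cluster minimum 5) are the standard settings for this kind of remote
homolog detection; all are keyword arguments.

## Trees

Motif instances are extracted per composition slot, aligned per motif
against the motif profile, and concatenated in composition order; a
subset of slots can be selected (e.g. only M16+M16C, shared by the three
M16-type families, for the combined tree). The default tree builder is
neighbor joining on Poisson-corrected pairwise distances
(d = −ln(1−p) over shared non-gap columns, capped at 5), with rows sorted
by name so the result is order-independent, and negative NJ branch
lengths clamped to zero. An external approximate-maximum-likelihood tool
can be supplied as a callable; the built-in NJ is the default because it
is deterministic and dependency-free, which the test suite relies on.

Midpoint rooting finds the tip pair at maximal path distance
(deterministic tie-break by leaf name) and places the root halfway along
that path, keeping internal-node labels (supports) as opaque strings. It
is idempotent and the two diameter endpoints end up equidistant to within
1e-9; all-zero-length trees have no midpoint and are returned as given,
with a warning.

Misclassification on a labelled tree is counted against each family's
*core clade*, defined reproducibly as the clade maximising the F1 score
between clade leaves and family members (ties prefer the smaller clade):
`misclassified` counts members outside the core clade, `foreign`
non-members inside it.

## Distance to the closest eukaryote

Per bacterial species and family three metrics are computed against the
eukaryotic homologs on the family tree: `dist_E` (sum of branch lengths),
`dist_T` (number of internal nodes on the path; cherry partners count 1,
and the count includes the traversed ancestor even when it is the root)
and `dist_S` (log10 of the best E-value of the bacterial sequence
searched against the eukaryotic set; E-values floored at 1e-300; log base
10 does not affect ranks). A species with several homologs contributes
its minimum (per-species reduction; a per-homolog view can be derived
from the same table). Missing values — species absent from a tree, or no
similarity hit — stay missing and are excluded per metric, never imputed.

`top_k` takes the k smallest distances per family and metric with ties
broken by species id; `pan_top_k` is the union over the metrics, so its
size lies in [k, 3k]. The resistant-vs-other comparison is a one-sided
Mann–Whitney rank-sum test (alternative: resistant distances smaller)
with the rank-biserial effect size 1 − 2U/(n₁n₂); groups with fewer than
two observations are reported as not computable. The choice of a
rank-sum test is an assumption of this package and is recorded in the
report object.

## Co-occurrence

The presence matrix marks a species/family cell true when at least one
homolog exists; all-false rows are kept. Enrichment crosses "carries both
peptidases of a pair" with "is AMP-resistant" in a 2×2 table and applies
the exact conditional (Fisher) test, two-sided by default with a
one-sided option. Resistance is a genus-level flag (every species of a
flagged genus counts as resistant). The resistant group is compared
against the *other* (non-resistant) species of the clade — the exclusive
contrast; the inclusive contrast against all species can be formed from
the same matrix. Raw p-values are reported for all 6 family pairs ×
clades without multiplicity correction, so users can correct as they see
fit.

## Logo statistics and the catalytic motif

Column information is log2(20) minus the Shannon entropy of the non-gap
residue distribution (uniform background); residue height = frequency ×
information; stack width = 1 − gap fraction. `-`/`.` are gaps, `X` is
missing data excluded from frequencies. No small-sample correction is
applied by default (keeping the analytic identities exact); the standard
(|A|−1)/(2·ln2·n) correction is available behind a flag. The catalytic
zinc-binding motif scanner reports every position with H, x, x, E, H
followed by a spacer of 76 residues (± a tolerance, default 0; tolerance
2 absorbs small indels near the motif) and a final E.

## The synthetic generator

The generator emulates the real study inputs — reference proteomes with
taxonomy and resistance annotations — at desk scale, with events known
exactly.

**Species tree.** Ultrametric, binary, depth 1.0. A fixed backbone splits
bacteria from archaea+eukaryotes at t = 0.15 and archaea from eukaryotes
at t = 0.35; clades are grafted as monophyletic subtrees with their most
recent common ancestors at t = 0.5 and random coalescent-style internal
join times. Bacterial inter-clade joins all finish by t = 0.25 so that
every clade has a clade-pure stem branch alive at the scripted transfer
time. Resistance is assigned to whole genera (3 species each) to realise
the requested per-clade resistant fraction.

**Gene families.** A Gillespie birth–death–transfer sweep runs forward
along the species tree: per gene lineage, duplication, loss, and (on
purely bacterial branches) transfer to a uniformly chosen contemporaneous
bacterial branch, at the specified per-unit-length rates. Scripted EGT
events copy a random donor-clade lineage onto a named recipient branch
(typically `stem:Eukaryota`) at an absolute time. Families originate as a
single lineage above the bacterial ancestor, so eukaryotes carry the
family only through scripted EGT. Every event is logged; the extant gene
tree is pruned from the full history. The per-leaf expected copy number
is exp((dup − loss)·T), which the tests verify by simulation.

**Sequences.** The family root sequence concatenates its domain blocks —
family-specific variants of the motif-library consensus (25% of positions
re-drawn deterministically per family; catalytic positions protected) —
flanked and separated by random linkers (default length 15). Along each
branch, sites substitute with probability 1 − exp(−site_rate · multiplier
· length), uniformly over the 20 amino acids; blocks use the core
multiplier (default 0.3), linkers the linker multiplier (default 1.0),
and linker lengths are re-drawn from a Poisson per branch, creating
alignment gaps. Whole-block deletions are applied per terminal lineage at
probability 1 − exp(−block_loss_rate · root-to-tip path): a heritable
per-branch process has the same expectation but a single early loss wipes
entire clades, making per-seed corruption far exceed the intended noise
level, so the terminal-lineage form was chosen to keep gene corruption
independent. The designated M16-like block embeds the catalytic pattern
(H at 3, E at 6, H at 7, E at 84 of the block).

**Default study conditions.** 6 bacterial clades × 10 species (alpha,
gamma, terra, cyano, fcb, pvc; resistant fractions 0.4/0.4/0.2/0/0.2/0),
2 eukaryotic clades × 6, one archaeal clade × 2 — 74 species. Four
families with one EGT each into the eukaryote stem at t = 0.3 (donors:
MPP←alpha, OOP←gamma, PreP←terra, SPP←fcb), duplication/loss rates tuned
to the observed abundance ranking (OOP most duplicated, PreP and SPP
frequently lost in bacteria), site rate 0.3/unit, block loss 0.05/unit,
plus 5 random background proteins per species as search decoys. These
sizes keep a full end-to-end run around a minute on one CPU while leaving
every downstream contrast (donor recovery, composition filtering,
co-occurrence) statistically visible.

**What the generator does not emulate.** Realistic substitution matrices
or site-rate heterogeneity, indels inside domain cores, genuine
correlation between resistance and donor proximity (resistant genera are
placed at random within clades, so resistant-vs-other comparisons on the
fixture behave as null cases), and the 8,340-proteome scale of the real
data. Passing tests therefore demonstrate correctness of the machinery
and recoverability of scripted signals, not biological conclusions.

**Randomness.** One root seed; per-family streams are spawned via
`numpy.random.SeedSequence`, so adding a family leaves the others
unchanged. Identical spec + seed gives byte-identical fixtures and output
tables (sorted writes throughout).

## Numerical choices and degenerate inputs

Ties are broken lexicographically everywhere a choice is needed (top-k,
closest eukaryote, diameter pair, cluster merging, primary family).
Zero-length trees root arbitrarily with a warning; empty groups in the
sample-set reducer are skipped with a warning; degenerate 2×2 margins
give p = 1 with an undefined odds ratio; single-sequence profile clusters
are flagged degenerate. NJ negative branch lengths are clamped to zero;
alignment distances are capped at 5 substitutions/site.

## Known limitations

The built-in NJ is adequate for the simulated divergences but is not an
approximate-ML method; very short motif alignments can leave deep family
relationships unresolved. The E-value-based `dist_S` saturates for nearly
identical sequences. The misclassification count depends on the max-F1
core-clade definition; other reasonable definitions (e.g. maximal pure
clades) give different absolute counts on poorly sorted trees.
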
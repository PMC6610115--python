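# Methods

`genorigin` asks a single question of three proteomes: for each gene of a
focal species, does its history look like the host lineage's or like the
symbiont lineage's?  The package grew out of the secondary-endosymbiosis
setting — a focal alga suspected of carrying a symbiont-derived nucleus,
bracketed by a host-lineage reference (a pelagophyte-like taxon, "A") and a
symbiont-lineage proxy (a diatom-like taxon, "P") — but the machinery is
generic to any three-taxon origin-attribution problem.

## The attribution model

For a single-copy orthogroup spanning the focal species N and references A
and P there are exactly three resolved rooted triplet topologies,
distinguished by which pair is sister.  The classifier reduces gene-tree
inference to a nearest-pair decision on the three pairwise distances
(d_NA, d_NP, d_AP):

* **Pattern I** — d_NA smallest: the focal gene is nearest the host-lineage
  reference; host-nuclear origin.
* **Pattern II** — d_NP smallest: nearest the symbiont-lineage reference;
  symbiont-nuclear origin.
* **Pattern III** — d_AP smallest: the two references are sisters and the
  focal gene is the outgroup; also counted as evidence against shared
  ancestry with the host reference, hence symbiont origin.

This three-way minimum is exactly the decision made by constraining a
hierarchical clustering of the three sequences to pairs, but stated on
explicit distances so it can be tested.  Which of Patterns II/III a
discordant gene falls into depends on rooting assumptions the distances
cannot resolve; the pair {II, III} is therefore interpreted jointly as
"far from the host reference".  The host/symbiont evidence tally compares
Pattern I against Patterns II + III and returns `symbiont-dominant`,
`host-dominant` or `indeterminate`.

Orthogroups with more than one member in any species are tallied as
`MULTI_COPY` and never classified — paralogy confounds the nearest-pair
logic, so these groups are reported, not interpreted.  If the two smallest
distances differ by less than a tie tolerance (default 1e-12, i.e. exact
ties only) the triplet is `UNRESOLVED`.  Counts of all five labels always
sum to the number of input groups.

Distances are p-distances from pairwise global alignments — the mismatch
fraction over columns that are gap-free and `X`-free — optionally mapped to
expected substitutions per site by the 20-state Poisson-type correction
`d = -(19/20) ln(1 - 20p/19)`.  The correction is monotone below its
saturation point (p = 0.95, where the estimate is reported as infinite), so
it cannot change a nearest-pair decision and defaults to off.

## Homology search and orthogroups

The search stage is exhaustive, not seeded: every query/subject pair gets a
full affine-gap Smith-Waterman score (BLOSUM62 by default; gap of length k
costs `open + (k-1)·extend`, defaults 11/1; `X` scores 0 against everything
and is excluded from identity counts).  Significance uses the Karlin-Altschul
form `E = K·m·n·exp(-λS)` with the common gapped-BLOSUM62 constants
λ = 0.267, K = 0.041 and a retention threshold of E < 1e-5; m is the query
length and n the total residue count of the subject proteome.  These
constants approximate what a database-search tool would report and are
configurable; the threshold mirrors standard practice for this kind of
screen.

Throughput comes from a subject-batched score-only kernel (numba): the DP
recurrence is vectorized across a lane of 128 subjects with int16
arithmetic and a per-batch substitution profile, reaching roughly 1.5
billion cells/s on one core.  Scores switch to int32 lanes automatically
when `min(len)·max_diagonal_score` could overflow int16.  Single-pair
alignments with traceback (used for distances, identity, coverage) go
through Biopython's `PairwiseAligner` configured to the identical scoring
convention; the test suite checks the two routes against each other and
both against brute-force enumeration of all alignment paths on short
sequences.  The canonical reported alignment is `PairwiseAligner`'s first
optimal traceback, which is deterministic.

Orthogroups are connected components (union-find, deterministic ordering) of
the union of the three cross-species reciprocal-best-hit sets.  Pure
cross-species RBH is structurally blind to recent within-species duplicates:
a duplicate is never any other species' best hit, so it would float free and
its family would pass as single-copy.  The builder therefore accepts an
optional fourth edge set of within-species in-paralog pairs, which the
pipeline computes for the focal species: a reciprocal-best non-self pair
within a species counts as a duplication only if both members have a
threshold-passing cross-species ortholog and the pair's score is at least
the weaker member's ortholog score (the InParanoid anchoring — a copy born
after speciation is necessarily closer to its twin than to any ortholog).
The anchoring matters: in a large proteome, two unrelated genes that both
lack true paralogs can be mutual best within-species hits by chance, and
without the bound such a pair would falsely merge two families.  A genuine duplicate then joins its family's component and flags
it multi-copy.  This is the package's own self-contained stand-in for
MCL-style orthology clustering; on clean data the components coincide, on
real data MCL-style tools are more permissive.

The Venn partition is independent of orthogroups: each focal gene is
assigned to unique / host-only / symbiont-only / both by the presence of at
least one threshold-passing hit against each reference proteome, so the four
categories always sum to the focal proteome size.

## Toolkit screening

A toolkit gene is defined by one or more reference sequences, optional decoy
paralogs, and a category tag.  Screening selects the best hit over all
reference queries passing the E-value threshold and a reference-coverage
filter (default 0.7 of the reference length — a stated, configurable guess
standing in for an unquantified "full-length" requirement), then assigns
the candidate to the nearest sequence among references and decoys by
Poisson-corrected global-alignment distance.  Present requires the nearest
neighbor to be a true reference; a candidate nearer a decoy is reported
absent with the decoy named.  This reproduces the cohesin disambiguation
(a meiotic-cohesin hit that is really the mitotic paralog Rad21 must not
count as Rec8) as a two-class nearest-neighbor decision instead of tree
inference — adequate because the decision is binary and the decoy is, by
construction, a known alternative explanation for the hit.

Downstream rules: the sexual-reproduction verdict is `sexual` iff at least
`threshold` toolkit genes are present (default 6, boundary inclusive; the
threshold base — whether the separately handled cohesin gene counts — is the
caller's choice of which calls to pass in); flagellar-style category tables
are summed per species and compared as a ratio of totals.

## The simulator

`simulate_dataset` generates the ground-truth mixtures every downstream
stage is tested against: single-copy triplet families (root sequence evolved
along one of the three topologies), species-unique genes (fresh random
sequences), multi-copy families (a within-focal duplicate at a configurable
distance), and toolkit genes with planted present / decoy-only / absent
statuses.

Substitution follows a 20-state uniform (Jukes-Cantor-type) model sampled
directly from the exact transition distribution: with probability
`exp(-20t/19)` a site keeps its residue through ancestry, otherwise it is
redrawn uniformly over all 20 letters (multiple hits included).  The
expected p-distance after total path length t is `(19/20)(1 - exp(-20t/19))`,
giving the closed form the Monte-Carlo tests check.  The model was chosen
over an empirical exchangeability matrix deliberately: the classifier only
consumes relative distances, and the uniform model is the one whose
distances have an analytic inverse.

Defaults, chosen once as the package's standard conditions: 1000 families at
topology proportions (0.26, 0.26, 0.48) — the dual-homolog mixture the
method is built to resolve; terminal and internal branches 0.3
substitutions/site (sister pairs ~0.6 apart, non-sisters ~0.9, comfortably
separated at length 300 yet far from saturation); sequence length 300
residues (a typical protein); 50 unique genes per species and 50 multi-copy
families with duplication distance 0.5; toolkit homologs planted 0.2 from
their reference with decoys at distance >= 0.5.  Topology counts are
allocated by largest remainder (deterministic; ties by category order) so
truth counts are exact, not multinomial.  Per-family generators derive from
`SeedSequence(master_seed, spawn_key=(domain, index))`; a fixed master seed
reproduces the dataset byte for byte, and changing it changes sequences but
no count.

What the simulator does **not** emulate: indels (homologs are equal-length,
so real-data gap handling is exercised only by the alignment tests, not by
recovery tests), rate heterogeneity across sites or lineages, composition
bias, fragmentary gene models, and annotation noise.  Recovery results on
this generator validate the pipeline's logic and statistics, not its
robustness to those real-data pathologies.

## Numerical and reporting conventions

* Printed percentages round half-away-from-zero at the requested number of
  decimals, computed in exact decimal arithmetic (645/2478 -> 26%,
  264/303 -> 87.1%).
* All tie-breaks are deterministic and documented: best hits by maximal
  score then lexicographic subject id; orthogroup ids by smallest member id;
  traceback via the aligner's canonical first path.
* Degenerate inputs: empty proteomes load with a warning; empty sequences
  align with pure-gap alignments scored by the affine convention; an
  all-`X` or zero-overlap alignment has p-distance 0 by convention (no
  comparable columns) and identity 0.
* Every pipeline run writes a manifest (config echo, seed, SHA-256 of each
  output) sufficient to reproduce it exactly.

## Problem sizes

The shipped verification suite runs the full pipeline on 1000 triplet
families plus 50 unique genes per species and 50 multi-copy families
(~1150-protein proteomes, ~4.4 million pairwise alignments, about six
minutes on one core); the distance law is checked with 500 replicates of
length 300, and alignment optimality on 200 short pairs against exhaustive
enumeration.  These sizes were chosen to give three-standard-error
statistical resolution on the recovered proportions while staying
comfortable to run on a laptop.

## Known limitations

* E-values are analytic approximations, not empirically calibrated to a
  specific search tool; absolute values differ from BLAST's, the ordering
  of hits does not.
* RBH components under-merge relative to MCL-style orthology on deep or
  asymmetric duplications; only recent in-paralogs of the focal species are
  rescued.
* The Pattern II / Pattern III distinction is convention-bound (see above);
  analyses should interpret them jointly as symbiont-origin evidence.
* With two reference species there is no outgroup inside the analysis: the
  method measures relative affinity, not rooted gene trees, and cannot
  distinguish symbiont origin from accelerated evolution in the host
  reference lineage.
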
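# Methods

## The marker system

Short interspersed elements (SINEs) retropose into essentially random
genomic positions and are almost never excised cleanly.  A SINE found at
the same orthologous position in two species therefore marks a shared
ancestor, and a set of such presence/absence markers can resolve
phylogenetic questions that sequence data leave ambiguous.  The rare
conflicts among markers arise mainly from incomplete lineage sorting
(ILS): an insertion still polymorphic at a speciation event can fix in a
set of descendant lineages that is not a clade.  `retroscreen`
implements the computational workflow around such markers: locus
selection and extraction, alignment screening, significance evaluation,
and simulation.

The default study system is the rodent phylogeny question the workflow
was built for: does the beaver (Castoridae) group with the kangaroo rat
(Geomyoidea) as Castorimorpha, and does Castorimorpha belong to the
mouse-related clade (Myodonta + Anomaluromorpha + Castorimorpha)?  The
default species tree is
`(((mouse,(beaver,kangaroo_rat)),guinea_pig),ground_squirrel)` with
guinea pig and ground squirrel as outgroups.

## Locus selection and extraction

RepeatMasker `.out` tables are parsed with coordinates preserved as
written (1-based inclusive) and converted once to the internal 0-based
half-open convention.  Rows sharing an element ID are merged into single
insertions.  Family selection matches the repeat *name* first and the
*class* second, so a class label such as `SINE/ID` selects all ID
subfamilies while `B1F` selects one family; the default family set is
{B1F, PB1D7, PB1D9, PB1D10, PB1D11, SP-D-Geo, SINE/ID}, the families
active on the lineage leading to beaver.

An element qualifies as potentially informative when both flanks to the
contig edge reach `min_flank` (default 50 nt, the room needed to place
PCR primers).  The comparison is inclusive (>= 50) by default; a
`strict` switch makes it exclusive for exact agreement with a ">50 nt"
reading — the difference affects only boundary loci.  Extraction takes
`min(available flank, extract_flank)` per side; the `extract_flank` cap
defaults to 250 nt, enough for primer placement around the ~200–300 nt
informative span of a rodent SINE locus.  Rows flagged as overlapped by
a higher-scoring match are kept but flagged; selection can exclude them.

## Presence/absence screening

Each selected element on the reference is projected through the AXT
blocks of every 2-way alignment.  Per element and taxon:

- `covered_fraction` — fraction of the element's reference positions
  inside any alignment block; below `min_coverage` (default 0.80) the
  locus is *uncovered*.
- `gap_fraction` — fraction of covered element columns opposite a query
  gap.  *Absent* requires strictly more than `absence_threshold`
  (default 0.70, the ">70% adjusted to a gap" rule; the boundary value
  0.70 is never absent).  *Present* requires strictly less than
  `presence_threshold` (default 0.30).  Between the two the call is
  *ambiguous*.

The presence threshold and minimum coverage are not part of the
original screening protocol, which resolved presence by manual
alignment inspection; they are exposed parameters whose defaults keep
the present/absent calls roughly symmetric and exclude fragmentary
alignments.  Manual misalignment review is likewise out of automated
scope — the screen writes per-candidate state tables for human review
instead of attempting to automate a judgment that was made by eye.

Loci are discarded unless *flank-clean*: no other annotated repeat may
overlap either 50-nt flank window by more than 10 nt (inclusive — an
exact 10-nt overlap passes).  Pattern classification then matches the
per-taxon states against a configured table of hypothesis patterns
(e.g. kangaroo rat(+)/beaver(+)/mouse(−)/outgroups(−) for
Castorimorpha).  Absence in the outgroups defines the plesiomorphic
state; a locus present in an outgroup, or with any required taxon
ambiguous/uncovered, is *uninformative*.  A locus present in a
non-nested subset of two or more ingroups that matches no hypothesis is
*conflicting*; presence in all ingroups is uninformative for the
trichotomy (the insertion predates it).

## Significance test

Markers supporting the three resolutions of a trichotomy are counted as
`[n1 n2 n3]`.  Under the polytomy null each marker supports each
topology with probability 1/3, so the counts are
Multinomial(n; 1/3, 1/3, 1/3).  The directional statistic is the focal
excess `D = n_focal − max(others)`, chosen because it is symmetric in
the two alternatives and reproduces the published no-conflict behaviour:
for `[n,0,0]` the only outcome at least as extreme is all-focal, giving
`p = 3^-n` exactly (1/729 ≈ 0.00137 for six markers).  The tail
`P(D* ≥ D)` is computed by exact integer enumeration of all compositions
for n ≤ 25 and by the same summation in log space above; the full pmf of
`D` is exposed for testing.  The multidirectional test evaluates all
three topologies as focal and declares the trichotomy resolved when
exactly one p-value falls below `alpha` (default 0.05; the original
report states bounds, not a chosen level).  The population-genetic
extensions of the original framework (Wright–Fisher fixation
probabilities, hybridization tests, four-lineage problems) are not
implemented.

## Simulator

The generator draws a uniform-random root genome (default 100 kb — large
enough that a handful of loci with 250-nt flanks are sparse, small
enough that every test runs in seconds), then walks the species tree
applying per branch:

- substitutions under a single-parameter equal-rates model (default
  0.02 per site per unit branch length; with the default tree depths
  this produces roughly 5–25% pairwise divergence, the range spanned by
  the real rodent comparisons). The screen reads only gap patterns, so
  a richer substitution model would add nothing it can detect.
- SINE insertions from a built-in library of seven mock families
  carrying the rodent family labels (75–160 nt consensus each), Poisson
  with default rate 2 per unit branch length, or exact per-branch counts
  when a controlled history is requested.
- ILS: with probability `ils_prob` (default 0.05 — conflicts are rare in
  real marker sets) an internal-branch insertion is retained by a random
  proper non-empty subset of that branch's descendant taxa.

Every nucleotide carries a unique site identity, so orthology is known
exactly and pairwise alignments are *reconstructed from truth* rather
than computed: shared sites form aligned columns, lineage-specific sites
sit opposite gaps.  Aligned columns whose windowed identity (101-column
window over aligned columns) drops below 0.5 are removed and the
alignment splits into blocks, emulating the failure of netted
whole-genome alignments over diverged sequence; this — not the
substitutions themselves — is what degrades screen recall as divergence
grows.  Insertions are placed in disjoint 1-kb slots (uniform unused
slot, uniform position in the slot interior), so simulated loci never
overlap and are flank-clean by construction; SINE pile-ups, nested
insertions, target-site duplications, and 5'-truncation are deliberately
not modelled.  Consequences: passing screens demonstrate correct
coordinate projection, calling, and classification, not robustness to
repeat-dense neighbourhoods or alignment artefacts, which the real
protocol handled by manual curation.

A fixed seed makes every emitted file bit-identical across runs.

## Assembly statistics

`assembly_stats` filters contigs below 200 nt (the assembly's minimum
contig setting), then reports both Nxx lengths (length of the contig at
which the descending cumulative length reaches x% of the total) and Lxx
counts (how many contigs that takes) for x in {25, 50, 75}.  Published
descriptions sometimes conflate the two; both are computed and labelled
unambiguously, since Nxx must be non-increasing and Lxx non-decreasing
in x.

## Scale and external data

The real study screened 133,796 assembled contigs, found >13,000
embedded SINEs, extracted 3,780 candidate loci, and sifted screening
candidates (16/14/26 for the Castorimorpha alternatives, 12/13/33 for
the mouse-related-clade alternatives) from multi-gigabyte UCSC 2-way
alignments.  Reproducing those numbers requires the deposited assembly,
its RepeatMasker table, and the UCSC alignment downloads — external
data this package does not ship.  The test suite instead verifies every
rule on simulated data with known truth, and verifies the published
accounting identity (the seven family counts sum to 3,780).  Given the
external inputs, the same `fastcoex-extract` and `screen` commands apply
unchanged.

## Numerical and degenerate-input choices

- One internal coordinate convention (0-based half-open); conversion
  only at file boundaries.
- Locus IDs are pure functions of coordinates, never counters.
- Empty annotation tables parse to empty lists; an interval projected
  entirely between blocks is uncovered, not an error; zero markers make
  the significance stage report "no markers" rather than a p-value.
- The exact/log-space crossover in the significance test is at n = 25;
  both branches agree with the 3^-n closed form at the boundary.
- Screen output order is always `(seq_id, start)` and pipeline JSON is
  key-sorted, so fixed-seed reruns are byte-identical.
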
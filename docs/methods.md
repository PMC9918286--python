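# Methods

## Satellite model

A satellite is a head-to-tail tandem array of a repeat unit of 10–200 nt
with at least four copies.  Copies are imperfect: they carry substitutions
and occasionally differ in length.  The pipeline treats a satellite as a
genomic interval plus an ordered partition into copies, and summarises its
internal regularity with two statistics: *same-length fraction* (share of
copies whose length equals the modal unit length; arrays below 0.6 are
discarded as too irregular) and *similarity* (mean pairwise ungapped
identity over the same-length copies; undefined, reported NA, with fewer
than two such copies).

Coordinates are 0-based half-open in memory and 1-based inclusive in every
table, matching genome-browser convention.

## Detection

**Seeding.**  Every primitive decamer — one with no tiling period ≤ 5, so
microsatellite-degenerate seeds like `ACACACACAC` never fire — whose
occurrences recur ≥ `min_copies` (4) times within a window of `window_nt`
(800) bases is clustered.  Occurrence runs split at gaps wider than the
window, so two arrays of the same family elsewhere on the chromosome seed
separate candidates.  Overlapping clusters from different decamers merge
into one candidate region.  k-mers containing N never seed; N matches
nothing anywhere in the pipeline.  With these defaults, units of 10–200 nt
are guaranteed four seed occurrences inside one window; detection runs on
the forward strand only, since a tandem array is its own array on the
reverse strand — strand matters only for family alignment.

**Unit length** is the modal spacing between consecutive occurrences of
the clustered decamers, pooled over all decamers of the region, ties
toward the smaller length.  Pooling matters: a single decamer can occur
twice per unit and alone would vote for split spacings.

**Anchoring and boundaries.**  The array core is anchored at the first
occurrence that starts a modal-spacing pair (a stray off-array occurrence
of a unit decamer can extend the candidate region but must not anchor the
core).  Whole units are annexed left and right while they match the
running majority-rule consensus at ≥ `extension_min_identity` (0.7 — loose
enough for the divergence real arrays show, strict enough to stop in
random flank).  Each boundary is then refined at base resolution in three
steps: extend while the trailing 12 bases carry fewer than 7 consensus
mismatches (random flank reaches that density within a dozen bases;
tolerable within-array divergence never does), trim back to the last run
of 8 consecutive consensus matches (a chance 8-run in flank has
probability 4⁻⁸ per position), then take single matching bases.  On a
perfect array this lands exactly on the tandem-span edge; at 5%
substitution noise it stays within a few bases.  The span is partitioned
into unit-length copies from the left edge; a terminal remainder shorter
than half a unit is absorbed into the last copy, a longer one stands as a
short copy of its own (so an array of 133 full copies plus a 31-nt partial
copy reports 134 repeats).  Nested or overlapping delimitations keep the
longer span.

## Family clustering

Tandem units are equivalence classes under cyclic rotation and reverse
complement.  The pairwise score of two unit consensuses is a global
Needleman–Wunsch alignment (match +1, mismatch −1, linear gap −2)
maximised over every rotation of either sequence on both strands,
normalised by the shorter unit length and clamped to [0, 1]; a perfect
match of the shorter unit scores 1 and unrelated random units score ≈ 0
(the raw score of unrelated DNA under this scheme is usually negative).
Maximising over rotations of *either* argument makes the score symmetric
by construction.  Rotation/strand arg-maxes break ties toward the smallest
rotation, then the forward strand.  Pairs whose unit lengths differ by
more than 25% of the longer unit are assigned score 0 without aligning —
cheap, and wide enough that the 31–35-nt length spread seen within real
families stays mergeable.

Satellite consensuses (majority rule over same-length copies, which the
detection phase has already placed in a common frame) are clustered by
agglomerative average linkage: repeatedly merge the cluster pair with the
highest mean inter-cluster score while that score ≥ 0.6.  Average linkage
is the stable conventional choice where the clustering granularity is set
by a single threshold.  Families are named `Fam_a_b_c` with a = 1..F by
descending member count (ties: ascending repeat size, then genome position
of the first member), b = family consensus length, c = member count.  The
family consensus rotates/flips every member into the frame of the first
member and takes a per-column majority over members of the modal length;
b comes from this consensus rather than any single member because members
vary in unit length.

Clustering operates on per-satellite consensuses, not on individual
repeat copies: the consensus is the natural summary once copies are
phase-aligned, and it keeps the score matrix quadratic in satellites
rather than in copies.

## Annotation

Location classes are exon > intron > intergenic with ≥ 1-nt overlap
deciding each step; exons of all transcripts of a gene are pooled, since
transcript-level assignment is not needed for a three-way split.  Gene
models come from GFF3 `gene`/`exon` records via gffutils; interval queries
use interval trees.  A chromosome absent from the annotation classifies as
intergenic with a warning rather than an error.  Transposon/repeat
annotation is consumed as BED4; a satellite reports the labels of every
interval it overlaps.

## Quantification

Reads are matched to reference windows of satellite ± 250 nt (clipped at
contig ends).  Matching is seed-and-extend: exact 12-mer seeds nominate
candidate windows; each candidate is scored by a semi-global alignment of
the whole read inside the window (edlib), on both strands, with identity =
matches / alignment columns, so gaps count against identity.  For reads of
≥ 52 nt at the 97% identity cut-off, a pigeonhole argument guarantees an
exact 12-mer survives the permitted mismatches — seeding therefore retains
exactly what a full dynamic-programming scan over all windows retains,
which the test suite verifies directly.  A minimum aligned span of 90% of
the read length is enforced (configurable); libraries are treated as
unstranded.  Hits landing entirely in the flank still count for the window
— flank transcription is part of the signal — but carry a `flank_only`
flag.

Per read, only the hit(s) tied at the maximum identity are counted, one
count per tied window: when several family members match a read equally
well it cannot be attributed to one of them.  A read spanning no satellite
window at the thresholds simply goes uncounted.

RPKM = hits · 10⁹ / satellite length / library size, with the library size
taken as the total read count of the sample's FASTQ.  Tissue-level values
are sums over the tissue's samples — hits summed and RPKM summed, not
recomputed from pooled counts, so each sample keeps its own library-size
normalisation.  A satellite is flagged positively transcribed in a tissue
when its tissue RPKM exceeds that tissue's mean RPKM over all satellites;
this sidesteps any fixed low-count noise threshold, which the data cannot
support.

## Coverage profiles

Depth at a position is the number of retained hits covering it, pooled
(not averaged) over the tissue's samples.  Tied multi-window reads
contribute to every tied window's profile, consistent with counting.
Rendering uses one panel per tissue with the conventional colors; vertical
scale is per-panel by default with an option for a shared scale.

## Synthetic data

The generator is the test bed: every output is a pure function of
(spec, seed).

* **Genomes.**  i.i.d. background at a chosen GC (default 0.36, nematode-
  like), with arrays written over the background at stated positions.
  Copies are mutated per spec (per-base substitutions, per-copy 1-nt
  indels); an array can be truncated so its last copy is partial.  The
  eight bases just outside each array edge are resampled to break the unit
  periodicity, making the planted span the *maximal* tandem span: in pure
  i.i.d. background the true tandem structure would extend past the
  nominal edge with probability ~1/4 per base, and "exact boundary
  recovery" would be ill-posed.  Gene models are emitted so each planted
  array's location class holds (intronic arrays sit inside a gene span
  between flanking exons; exonic arrays inside an exon).
* **Helitron-style loci** follow the canonical layout of a complete
  rolling-circle transposon: 15-nt satellite, 32-nt satellite, 5′
  conserved region, central gene, 31-nt satellite in direct contact with
  the gene end, 3′ conserved region; the defaults echo a real complete
  element (gene 4874 nt, satellites 1179/351/76 nt).  Only the structural
  layout is simulated, not real Helitron sequence content.
* **Reads.**  Tissue-stratified single-end reads drawn from satellites
  with probability ∝ per-tissue expression weights, optionally from
  weighted sub-regions (emulating non-uniform transcription), uniform
  start within the region, random strand, substitution errors only
  (read-level indels are off by default).  True per-satellite counts,
  read origins and library sizes are recorded.
* **Default scene.**  20 satellites in 3 families (10 members × 35 nt,
  6 × 94 nt, 4 × 21 nt) across two 60-kb chromosomes; 12 intergenic, 5
  intronic, 3 exonic; 4 tissues × 2 samples × (default) 1000 reads of
  100 nt.  Family master units are sampled until mutually dissimilar
  (pairwise cyclic score < 0.4), so the planted partition is unambiguous.
  Each member's unit mutates a member-specific block of k = max(2, L/12)
  unit positions, disjoint across members: every member pair then differs
  at exactly 2k positions — few enough that all within-family scores stay
  above the 0.6 clustering threshold, many enough that a 100-nt read
  always falls below the 97% identity cut-off on any sibling and maps
  uniquely.  Roughly 30% of members are placed as reverse-complement
  copies.  Expression weights are log-uniform per tissue with one boosted
  tissue per satellite, neurons most often — echoing the tissue bias real
  satellite transcription shows.

What passing on this scene does *not* show: performance on real genomes
with nested or higher-order repeat structure, transposon-dense regions,
sequencing-error profiles beyond uniform substitutions, or read lengths
short enough to defeat the seeding guarantee.  A perfect tandem array is
additionally degenerate for read placement — any aligner ties across
copies — so sub-region localisation is only meaningful for arrays with
copy-to-copy variation, and the tests exercise it that way.

## Numerical choices and degenerate inputs

* Identity comparisons treat N as mismatching everything, including N.
* Float identity ties in best-hit assignment use a 1e-9 tolerance;
  identities are ratios of small integers and exact ties are exact.
* Majority votes (consensus building) break ties alphabetically (A < C <
  G < T), making all consensuses deterministic.
* Cluster merging breaks score ties toward the smallest cluster indices;
  family naming breaks rank ties by repeat size then genome position.
  Identical inputs and configuration give byte-identical tables.
* An empty genome yields an empty satellite list, not an error; a
  satellite with fewer than two modal-length copies reports similarity NA.

## Problem sizes

The default test and acceptance configuration uses two 60-kb chromosomes,
20 satellites, 8 samples × 300–500 reads, chosen to exercise every code
path at desk scale; detection, clustering and quantification each finish
in seconds.  All stages scale linearly in genome size and read count
except all-vs-all family scoring, which is quadratic in the number of
satellites with a cheap length pre-filter.

## Known limitations

* Boundary refinement assumes substitution-dominated divergence; an indel
  inside an array shifts the consensus frame and can shorten the reported
  span by up to a unit on the far side of the indel.
* No higher-order repeat structure, no repeat-library masking mode, no
  spliced alignment, no paired-end handling, no polyA selection modelling.
* Counts for near-identical family members are inherently shared (the
  maximum-accuracy tie rule); per-member expression is only identifiable
  when members have diverged.
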
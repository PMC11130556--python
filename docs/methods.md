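# Methods

## Distances

All distances are uncorrected p-distances: the number of differing sites
divided by the number of comparable sites for that pair (pairwise deletion).
No multiple-hit correction is applied anywhere in the characterisation path —
barcode distances are conventionally reported as raw percentages, and the
clustering threshold is defined on that scale.

Which columns are comparable is an explicit policy, because the alignment
viewers these matrices usually come from do not document their handling of
ambiguity codes:

* `strict` (default): a column is dropped for a pair if either sequence has a
  gap **or** any non-ACGT code there. Conservative and exactly reproducible.
  On the packaged barcodes the effect is at most 2 sites out of 652 per pair.
* `gaps_only`: only gap columns are dropped; two codes count as a match when
  their base sets intersect (Y matches C, differs from G).

Distances are stored as fractions in [0, 1]; percent formatting (one decimal,
half away from zero, values ≥ 10% with a trailing .0 printed as integers,
matching the style of published species accounts) is confined to reporting.
A pair with zero comparable sites has an undefined distance: it is stored as
NaN with a zero comparable count, and clustering refuses such matrices rather
than guessing.

## Per-species characterisation

For species *s*: *n* = number of records; max-intra = max of d over
conspecific pairs (undefined — "not applicable" — when *n* = 1); min-inter =
min of d over pairs (record of *s*, record of any other species), reported
with the neighbour's species name, ties broken lexicographically by species
name so output is deterministic. Nearest-neighbour relations are not forced
to be reciprocal.

The consensus is a per-column IUPAC majority call. Gaps are ignored within a
column (an all-gap column is dropped, so the consensus is gap-free);
ambiguity codes contribute their base sets to the observed pool but not to
the vote. A base is emitted when it is the unique most frequent unambiguous
call and holds at least the majority share (default 0.5) of unambiguous
calls; otherwise the minimal IUPAC code covering all observed bases is
emitted. The 0.5 default with tie→union behaviour reproduces the isolated
Y/R codes seen in published consensuses of small samples; a 100% rule would
produce far more ambiguity codes than published consensuses show.

## Delimitation

Objective clustering is single linkage: clusters are connected components of
the graph with an edge wherever d < t. The comparison is strict (a pair at
exactly t stays separate) — the boundary convention is arbitrary in the
methods this mirrors, so one was fixed and documented. The default threshold
is 3%, the conventional barcode-gap cutoff. Cluster ids are assigned in
first-seen record order. k(t) is non-increasing and partitions refine
monotonically in t; both properties are under test.

Ranked partitions: single-linkage merge heights h₁ < … < h_K partition the
threshold axis into intervals (h_i, h_{i+1}] on which clustering is constant.
Each such partition is scored by the relative width of its gap,
(h_{i+1} − h_i) / h_{i+1}, with the maximum observed distance standing in
above the final merge; candidates are sorted by score, ties to fewer
clusters. This is a transparent "ASAP-like" ranking of the same candidate
set a hierarchical gap method searches; it is deliberately **not** the
published ASAP score (probability-based, tied to its own implementation),
and outputs are labelled accordingly. The relative-gap statistic is noisy at
very small heights, where a sliver between two tiny merge heights can score
highly; rankings are therefore most meaningful when a real barcode gap
exists. Externally produced partitions can be read from TSV and scored the
same way, so results from tree-based delimitation tools can be compared
without reimplementing them.

Congruence against reference labels, per species: **congruent** — records
form exactly one cluster containing nothing else; **split** — ≥ 2 clusters,
none shared; **lumped** — one cluster shared with other species; **mixed** —
anything else.

## Diagnostic indels

The reading frame of a gap-free reference is the offset (0/1/2) minimising
internal stop codons under NCBI translation table 5 (invertebrate
mitochondrial: ATA = Met, TGA = Trp, AGA/AGG = Ser); codons containing
ambiguity codes are skipped in the stop count, ties go to the smallest
offset. Translation renders a codon as its amino acid when every resolution
of its ambiguity codes agrees, else X.

Shared deletions are maximal runs of columns where the reference has a base
and at least `min_share` of the other records have a gap (default 1.0: a
diagnostic character must be universal in the ingroup). Coordinates are
1-based inclusive alignment columns. A run is frame-preserving when its
length is divisible by 3; the verdict requires exactly one shared deletion of
the expected length (default 6 bp) overlapping the expected window (default
columns 450–510 — a window, not a point, because the flanking region is
variable enough that the exact homologous position is uncertain), carried by
every queried record; failures name the records lacking the gap.

The packaged fixture's full-length reference is synthetic: all seven packaged
barcodes carry the deletion, so a gap-free baseline is reconstructed by
re-inserting six neutral bases (two leucine codons, keeping the reference
frame stop-free) at the deletion site of the *P. villosa* sequence. It is a
detector baseline, not a biological sequence.

## Simulator

Sites evolve i.i.d. under Jukes–Cantor; a branch of length b (expected
substitutions/site) changes a site with probability
p = (3/4)(1 − exp(−(4/3)b)), uniformly to one of the three other bases.
Because per-branch transitions are exact JC kernels, path expectations
compose, and the closed form doubles as the calibration oracle.

The species tree is a random ultrametric built by sequential splitting.
Internal split heights are confined to the upper half of the root height, so
every leaf-pair path stays within a factor of two of the deepest one, then
the whole tree is rescaled so the mean leaf-pair path equals the JC branch
length whose expected p-distance is the configured interspecific divergence.
Keeping pairwise divergences in a narrow band preserves the barcode gap for
every species pair, not just on average — without the constraint a shallow
split can fall under the clustering threshold and there is no signal to
recover. Within species, records radiate star-like from the species
ancestor on terminal branches of half the intraspecific JC depth, so two
conspecific records sit at the full configured intraspecific divergence in
expectation. There is no within-species coalescent, no rate heterogeneity
and no indel evolution model: the generator's job is a controllable barcode
gap plus the bookkeeping features (ambiguity codes, a clade-restricted
in-frame deletion rendered as shared gap columns), not population-genetic
realism. Passing recovery tests therefore show the pipeline is correct under
its own assumptions; they do not show those assumptions hold for any real
dataset.

Defaults: 7 species × 5 records, 658 bp, intraspecific divergence 0.01,
interspecific 0.08, ambiguity rate 0.001 per record site, optional deletion
of 6 bp at column 476 — the regime of a well-separated multi-species
barcoding study, and small enough that the full suite runs in seconds. The
generator refuses configurations with intra ≥ inter (no gap to recover), and
identical configuration + seed yields byte-identical output.

## Numerical and interface choices

* Thresholds are fractions internally; the CLI accepts "3%" and "0.03"
  identically to remove the classic 0.03-vs-3 ambiguity.
* Single-linkage components come from `scipy.sparse.csgraph`, merge heights
  from `scipy.cluster.hierarchy`; the clustering semantics (strict d < t)
  are pinned by an exhaustive transitive-closure oracle in the tests.
* FASTA parsing via biopython; headers follow `>record_id|species` with a
  separate labels TSV as the canonical source of species assignments.
* Percent CSV matrices round-trip to within 0.05 percentage points (one
  decimal of a percent), which is also the precision of published values.

## Known limitations

* Specimen-level published values can only be approximated from per-species
  consensus sequences; recomputed interspecific minima can differ from
  specimen-level ones by a site or two (≈ 0.15 percentage points at 652 bp).
* The gap-ranked partition score is a heuristic stand-in for model-based
  partition ranking and has no probabilistic interpretation.
* The consensus caller is unweighted; published consensuses from
  chromatogram-aware tools may differ at low-coverage columns.
* `min_share` between 0 and 1 reports runs whose per-column share passes the
  bar even if no single record is gapped across the whole run; with the
  default 1.0 this cannot happen.
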
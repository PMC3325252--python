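# Methods

This note documents the models, default parameters, numerical choices
and known limitations of `bes_survey`, stage by stage, and describes
what the synthetic-data generator does and does not emulate.

## Coverage statistics

Library representation follows the classical clone-library model: with
`N` independent clones of mean insert `I` from a genome of size `GS`,
`P = 1 − (1 − I/GS)^N`.  `clarke_carbon_clones` inverts this to the
smallest integer `N` reaching a target `P`, guarding the ceiling against
floating-point edge cases by checking both neighbours.  Genome
equivalents discount empty clones and organellar contaminants, both
supplied as proportions; contamination itself is estimated as
positives/screened from colony-filter hybridization counts.  Reported
percentages are rounded half-up at two decimals; genome equivalents are
reported both exactly and rounded to the nearest integer.  The model
assumes uniform, independent clone sampling — real libraries are biased
by restriction-site density, which this package does not model.

## SSR detection

An SSR is a maximal perfect tandem run of a primitive motif of period
1–6: periods 1–3 need a run of at least 12 nt, periods 4–6 at least
four units; fractional trailing units count toward the length.
Implementation: for each period `p` the sequence is compared with
itself shifted by `p` (vectorised); maximal equality blocks of length
`L` are tandem runs of length `L + p`.  Runs are broken at N, a run
whose leading unit is non-primitive belongs to a smaller period, and
identical intervals arising at several periods are reported once under
the smallest period.  Motif classes merge a motif with its reverse
complement only — rotational phases stay distinct, which is how
trinucleotide classes such as GCC/GGC and CGC/GCG are conventionally
tabulated.  Density uses the full corpus (including masked and N bases)
as denominator.  Only perfect repeats are reported; mismatch-tolerant
repeat finders would count interrupted runs differently, so read-based
counts are slightly conservative on noisy data.

## Local alignment engine

One affine-gap Smith–Waterman core serves every stage.  A gap of length
`L` costs `gap_open + L·gap_extend` (defaults −5, −2; match +1,
mismatch −2; N matches nothing).  The dynamic program fills H/E/F
row-wise; in pure numpy the within-row insertion state is computed as a
prefix-maximum scan (valid because opening twice never beats extending,
given `gap_open ≤ 0`), and when numba is importable the same recurrence
runs as a compiled kernel — both paths produce identical matrices, and
the test suite checks scores against an independent plain-Python DP.
Large problems are narrowed first by exact k-mer seeds (default 12 nt)
clustered on diagonals; each cluster is aligned inside a padded window.
Problems up to 160,000 cells skip seeding entirely, so the optimum is
exact there by construction.  Translated search translates all six
frames, splits at stop codons (segments are aligned independently, not
penalised through stops) and reports hits in query nucleotide
coordinates with the frame recorded; scoring is BLOSUM62 with gap open
−11 / extend −1.

E-values use the Karlin–Altschul form `E = K·m·n·e^(−λS)` with the
standard ungapped nucleotide constants (λ = 1.28, K = 0.46) and common
gapped protein constants (λ = 0.267, K = 0.041) applied as
approximations, with `m·n` the product of the two sequence lengths
rather than database-effective lengths.  These E-values are internally
consistent thresholds, not replications of any particular search tool;
externally produced 12-column tabular alignments can be substituted at
every stage that consumes hits.  Discontiguous (spaced) seeds are not
implemented; searches needing that sensitivity can be supplied via the
tabular route.

## Known-repeat annotation

Reads are searched against a class-labelled library (RepeatMasker-style
`name#class/subclass` headers), both strands, with candidate pairs
prefiltered by shared k-mers.  Hits need ≥ 70% identity and ≥ 50 bp on
the read (defaults) and an E cutoff of 1e-5.  Fragments of the same
element on the same read, in consistent order and orientation, merge
into one element when separated by ≤ 100 bp on the read and ≤ 500 bp on
the element — the merging principle is that an element fragmented by an
insertion is still one element; the gap sizes are package defaults
chosen at the scale of nested insertions visible within single reads.
Masking lowercases (soft) or N-outs (hard) the fragment intervals;
masked bases can neither seed nor extend later searches, which makes
annotation idempotent.  Per-class base counts use interval unions per
read, so overlapping fragments are never double-counted; "interspersed
repeats" totals cover the transposon class groups (retroelements, DNA
transposons, unclassified), while satellites, small RNA and
low-complexity sections are tabulated alongside without joining that
total.  Low complexity is flagged by trinucleotide Shannon entropy
below 1.4 bits in 64 bp windows stepped by 32.

## Novel-repeat mining

The chain mirrors de novo repeat discovery from unassembled survey
reads:

1. **Self-comparison** of masked reads.  Candidate pairs share ≥ 3
   exact 14-mers (either strand, masked bases excluded); a pair counts
   as a match only if some alignment contains ≥ 100 consecutive columns
   at ≥ 90% identity and passes E ≤ 1e-50.  Match counts per read are
   symmetric, self-matches excluded.
2. **Selection** of reads with ≥ 6 distinct partners.
3. **Segment extraction.**  For each selected read, a per-base profile
   counts distinct partners covering the base; maximal runs with ≥ 6
   partners (≥ 80 bp) become segments.  This support profile is what
   separates the repeat portion of a read from flanking sequence shared
   only with same-locus reads, and keeps two repeat families that
   happen to sit near each other in the genome from being bridged into
   one cluster.
4. **Clustering and consensus.**  Single-linkage clustering joins
   segments aligning at ≥ 80% identity over ≥ 80 bp (k-mer prefiltered);
   each cluster is star-aligned to its medoid (highest total alignment
   score; ties to the lexicographically smallest read id) and a
   majority consensus is called over medoid positions with ≥ 50%
   occupancy, trimmed to the first/last passing positions.  Consensi
   outside 80–300 bp, or clusters with fewer than six distinct reads,
   are discarded.  This deterministic clustering replaces
   expectation-maximisation motif discovery: the deliverable (family
   consensi with support counts) is the same, and the procedure is
   exactly reproducible and oracle-testable.  The consensus orientation
   follows the medoid's strand and is therefore arbitrary per family.
5. **Known-database filtering** removes candidates with any nucleotide
   or translated hit at E ≤ 1e-4 against supplied databases.
6. **Extrapolation**: genome copies = ⌊support / sampled fraction⌋,
   where the sampled fraction defaults to corpus bases / genome size
   (clamped to 1 for over-sampled simulations, with a logged warning).

Because the minimal qualifying match (100 bp at 90%) sits near the E
cutoff for read-sized search spaces, very short families (≲ 120 bp)
are only detectable through longer or better-conserved copies; the
synthetic benchmarks therefore plant families of 150–300 bp.
Consensus length is also conservative: copies truncated at read ends
lower column occupancy near family edges, so consensi are trimmed
relative to the planted element while remaining ≥ 98% identical to it
over their length.

## GC / coding partition and GO tabulation

A "protein signature" is operationalised as a passing translated-
homology hit (the same filters as comparative mapping); signature
intervals are unions of hit spans per read.  GC excludes N from the
denominator, and the partition satisfies the identity that overall GC
is the base-weighted mean of coding and non-coding GC (tested to
5e-2).  Domain-model (HMM) searches are out of scope, so GO terms are
consumed as a provided read→term table and tabulated per namespace.

## Comparative mapping

Reads are placed on reference peptides by translated search; hits pass
three filters — identity ≥ 75%, E < 1e-20, aligned read coverage > 50%
of the full read length (masked bases included in the denominator) —
and the best placement per read is chosen by score, with deterministic
tie-breaking (lower E, then reference id, then leftmost coordinate).
Peptide-space placements are projected to genomic coordinates through
the single-exon gene annotation.  Clones whose two ends place on one
reference sequence within 500 kb (outermost coordinates) become paired
placements marking microsyntenous regions; pair orientation is recorded
but not enforced.  When exactly one end places in coding sequence, the
mate is rescued by nucleotide alignment against the ±500 kb genomic
window (identity and coverage filters apply; no E constraint inside the
window).  Collinearity blocks are extracted by repeated longest-chain
search over ortholog pairs (reciprocal-best peptide matches,
position-ranked per genome): chains must be strictly monotone in both
genomes (decreasing = inversion) with at most `max_gap = 2` skipped
genes per step per side; ties prefer fewer skipped genes, then the
leftmost start.  Chains shorter than two pairs are reported as
rearranged/absent genes.

## Synthetic data generator

Everything is a pure function of (config, seed) via one
`numpy.random.Generator`; identical seeds give byte-identical FASTA and
reports.  The generator emulates:

- background sequence at a configured GC (default 44%);
- repeat families planted as point-mutated copies of a random
  consensus at a per-copy divergence rate, non-overlapping;
- SSR loci as exact tandem runs whose flanks are adjusted so the
  planted locus is precisely the maximal run;
- single-exon genes back-translated from random peptides with
  GC-biased codon choice (default 90% G/C-ending codons), scattered by
  rejection sampling or tiled with intergenic gaps for gene-dense
  reference regions (in tiled mode the gene count acts as an upper
  bound and planting stops at the end of the genome);
- BAC clones placed uniformly with truncated-normal insert sizes, two
  inward-facing end-reads per clone (reverse end reverse-complemented),
  truncated-normal read lengths (mean 761, sd 120, bounds 100–1000 —
  echoing large trimmed Sanger BES sets), substitution errors at 0.2%
  per base (post-trim high-quality Sanger scale), and organellar
  contaminant clones at a configured fraction;
- a related reference derived by inversions, translocations (each
  moved segment becomes its own chromosome), deletions and insertions,
  with breakpoints snapped to intergenic midpoints so the annotation
  lifts cleanly, every operation recorded in a ledger, and an orthology
  table between original and lifted gene orders.

It does **not** emulate: quality values or chimeric clones, indel
sequencing errors, polyploid homoeologs, nested or truncated repeat
insertions, introns, or cloning bias.  Passing tests on this bed
demonstrate the pipeline's correctness and calibration under those
idealisations, not performance on real trace data.

## Benchmark designs and problem sizes

Two session-level benchmarks back the heavier guarantees, sized to run
the whole suite in a few minutes on one CPU:

- **Repeat benchmark**: 2 Mbp genome, 20 novel families (150–300 bp,
  25–45 copies, 3% divergence), three known families, 240 SSR loci,
  1,000 clones (~0.75× read coverage).  Checks: family-level recall and
  precision ≥ 0.9 (a candidate matches a planted family if it aligns at
  ≥ 90% identity over ≥ 80 bp in either orientation); SSR density
  recovered within 10% relative error; known-repeat fraction within 3
  percentage points.  A 200 bp control element injected into exactly
  five reads verifies the support rule exactly: each carrier has four
  partners, below six, so the family is never reported.  Control reads
  are chosen (from the truth tables) to carry no planted repeat and to
  share no ≥ 50 bp genomic overlap with any other read, so their only
  matches come from the injected element.
- **Synteny benchmark**: 600 kb gene-dense genome (tiled genes,
  420–500 aa peptides, 150–250 bp gaps), 250 clones of ~40 kb inserts,
  related reference with one 170–190 kb inversion and two
  translocations to new chromosomes; the pairing constraint is scaled
  to 100 kb.  The inversion is deliberately longer than
  `max_insert + insert_max`, so a clone straddling an inversion edge
  maps its ends ≥ 110 kb apart and cannot pair.  Clones are classified
  from the truth tables: *clean* (no breakpoint inside the insert),
  *spanning* (a breakpoint strictly between the two end-reads) and
  *boundary* (a breakpoint inside an end-read itself).  Pair recall is
  measured on clean clones (≥ 0.95); spanning clones must yield zero
  pairs; boundary clones are excluded from both sets, since a read
  straddling a junction is legitimately placed by its majority segment
  and the resulting pair reflects a real adjacency up to one read
  length.

Read-based SSR counting carries two small opposing biases the density
check tolerates: loci split or truncated at read boundaries (and
occasionally disrupted by a base error) are lost, while loci sampled by
two overlapping reads are counted twice.

## Numerical and reporting conventions

Coordinates are 0-based half-open internally; GFF3 output is the single
conversion site (start+1, end).  Tabular alignments follow the
12-column BLAST field order with 1-based inclusive coordinates and
`s_start > s_end` on the minus strand.  Percentages print at 1–2
decimals, densities at one decimal, matching how such surveys round;
the sampled genome fraction is reported unrounded (its half-up rounding
at one decimal is ambiguous exactly at x.x5).  All tie-breaks
(placement, medoid, chain extraction, majority votes) are deterministic
so reruns are byte-identical.  Report generation writes no timestamps
into the report body; logs go to standard error.

## Known limitations

- E-values are approximate (see above) and not comparable across tools.
- The seeded search can miss alignments whose identity is too low to
  share seed k-mers (≪ 80% over short spans); the thresholds used by
  every pipeline stage sit well above that regime.
- Single-linkage clustering can in principle chain two families through
  a read where they abut within the support-run resolution (~20 bp);
  at realistic repeat spacing this was not observed.
- Translated placement requires a read to cover > 50% of its length
  against a single peptide, so reads spanning gene boundaries or
  carrying stop-inducing errors near the centre may remain singlets;
  mate rescue recovers most affected clones.
- The simulator's genes are intronless; projecting placements through
  real multi-exon annotations would need a CDS-aware liftover.
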
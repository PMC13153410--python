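# Methods

## Model of peptide origin

A peptide of length *L* is said to originate from a provirus region if
some reading frame of that region contains a stop-free stretch whose
translation includes the peptide as an exact substring. The genomic
evidence for the origin is the **fragment**: the unique interval of
`3L` nucleotides whose coding-orientation translation equals the peptide.
This is deliberately strict — 100% identity over the full length, with
isoleucine and leucine kept distinct even though mass spectrometry cannot
separate them — so that every reported candidate has a literal coding
interpretation on the genome, and expression evidence can be attached to
an exact interval. Near-matches, binding affinity and spectral re-scoring
are out of scope.

## Database construction

Regions are loaded from FASTA (region-oriented sequence) plus BED
(0-based half-open on disk, converted to 1-based inclusive plus-strand
coordinates at the boundary; optional column 6 strand). When the BED
carries no strand, `annotate_strand` orients the sequence against the
reference genome window by position-wise identity; the threshold is 0.90,
and a region matching neither orientation is excluded with a warning
rather than guessed. A BED strand, when present, takes precedence.

Six-frame translation uses the standard genetic code; frames +1/+2/+3
read the region sequence at offsets 0/1/2 and −1/−2/−3 read its reverse
complement likewise. Only `N` is accepted as an ambiguity code; any codon
containing `N` translates to `X`, which matches no query residue — an
ambiguous base can therefore never create a peptide hit. ORFs are maximal
stop-free stretches, minimum length 1 amino acid by default (short ORFs
are harmless noise for substring search; the minimum is configurable).

Duplicate ORFs are collapsed per region at exact protein identity, with
the union of genomic placements kept on the survivor, so no searchable
sequence content is lost and placement totals are conserved. Collapsing
at less than 100% identity would delete sequence that the exact-match
filter needs; a similarity threshold is still accepted as a config option
for compatibility experiments.

ORF-to-genome localization is exact arithmetic rather than re-alignment:
the generator knows each ORF's frame and offset, so its placement is
computed directly and *verified* by extracting the placement's
coding-orientation DNA and translating it back — a round-trip that is
asserted at build time for every ORF and again for every emitted
fragment. This removes aligner-version nondeterminism from a step whose
answer is known exactly.

The database serializes to a single JSON key-value file with a format
name and version header; reload equality is tested. Liftover to other
assemblies parses UCSC chain files and maps an interval only when it
falls inside a single aligned block — an interval split across blocks or
covered by no chain is rejected with a reason (`split` / `unmapped`) and
reported, never silently dropped, because a peptide-coding window broken
by an alignment gap has no meaning in the target assembly.

## Personalization

A sample's VCF contributes single-nucleotide substitutions only (the
record's REF must match the region's plus-strand base — a mismatch aborts
with an error since it indicates an assembly mix-up). Records failing
FILTER (other than PASS/'.') are skipped by default; indels, MNVs and
symbolic alleles are counted and skipped. All passing SNVs inside a
region are applied jointly to one variant haplotype (one haplotype per
alternate at multi-allelic sites, varying one site at a time); genotype
and phasing fields are ignored — the model is accumulated somatic
substitution, not diploid genetics. Variant haplotypes are re-translated
in six frames; variant ORFs identical to a reference ORF of the same
region collapse onto it. Personalization is additive: reference ORFs are
never removed, even though a real variant could also destroy a reference
match — modeling loss would require genotype semantics that single-sample
somatic VCFs do not reliably carry.

## Peptide search

The canonical backend is exact substring search over ORF proteins:
the retained hit set of the method is by definition the set of exact
full-length occurrences, so substring scan *is* the specification, with
no seeding heuristics to drop short matches. The BLASTP backend (word
size 3, gap open 9, gap extend 1, PAM30, threshold 16, no compositional
statistics, window 15, e-value 0.05) exists for compatibility and is
post-filtered to 100% identity and full query length; it is tested to be
a subset of the exact backend and is never the reference path.

## Quantification

Counting is featureCounts-like with one deliberate deviation: an
alignment is assigned to **every** fragment it overlaps by at least
`min_overlap_bp` (default 1) aligned bases, strand-agnostic. Candidate
fragments routinely nest and overlap (the same window can encode a
peptide and a substring peptide), so largest-overlap disambiguation would
silently zero nested fragments. Defaults: duplicates and QC-fail reads
counted, MAPQ threshold 0, each alignment record counted independently
(a template mode counting a read pair once is available by flag).

Multi-mapping is a user choice. Default: only unique alignments count
(primary records with NH absent or 1), weight 1, and counts are integers.
Fractional mode: every alignment including secondaries contributes 1/NH,
so a read overlapping one fragment under each of its NH alignments
contributes total weight exactly 1; counts are reported to 2 decimals.

One counting job runs per sample with a configurable worker pool; the
merged fragment × sample matrix is identical for any worker count and
submission order (each sample's column is computed independently), a
failed sample withholds its column and is recorded in the task-status
JSON under the run's task id. Partial matrices from separate invocations
merge when their fragment sets agree and sample ids are disjoint.

Cohort aggregation sums tumor and normal groups; the most-expressed
fragment per peptide maximizes total reads (a flag switches ranking to
tumor reads), with ties broken lexicographically by
(chrom, start, end, strand) and all-zero peptides reported as `no read`.

## Reporting

Validation-ready sequences extract the fragment ± flank (default 60 nt
per side, clipped at contig bounds without padding) from the plus strand
and reverse complement the whole window for '−'-strand fragments, so the
coding window always reads in frame left to right; it is emitted both as
a separate column and as `UP[CODING]DOWN`. Every emitted coding window is
asserted to translate to its peptide at write time. The three summary
tables are (1) every fragment × sample count with sequences, (2) the
cohort-level most-expressed fragment per peptide, (3) the per-sample
argmax table with `no read` cells. The three heatmap layouts (peptides ×
groups; fragments × groups per peptide; fragments × samples per peptide)
use a monotone sequential colormap with counts annotated in cells, and an
optional zero-row drop.

## Synthetic data and what it shows

The simulator emulates the pipeline's inputs at toy scale: a 2-contig
random genome (10 kb per contig, GC 0.42), seven 240-nt provirus-like
regions, six query peptides, and 6 samples (3 patients × tumor/normal).
It plants, by construction: a peptide on a '+' region forward frame; one
in a reverse frame ('−' fragment); one on a '−' region; a 15-mer with a
nested 9-mer substring query ('−' strand, nested fragments); a duplicated
region giving the same peptide two loci plus NH=2 reads shared between
them; a one-residue decoy that exact search must never hit; and a
near-miss window that a planted SNV converts into a true coding window
for one sample. Codon choice in planting is deterministic
(lexicographically first codon per residue), and a generation-time
self-check scans all regions in six frames and fails if query peptides
occur anywhere other than the designed truth windows.

Reads (length 50) are *placed*, not sampled: per fragment and sample an
intended count (0–5, seeded) of unique reads is laid at stratified
positions overlapping the fragment, and per-fragment truth counts are
then recomputed by independent interval-overlap arithmetic over the
placed reads — so nested fragments' cross-overlaps are part of the truth,
and recovery tests demand exact equality, not statistical agreement.
The simulator does not model sequencing error, quality strings, splicing,
realistic insert sizes or expression-level realism; passing tests
demonstrate coordinate/counting correctness, not robustness to noisy
alignment. All outputs are byte-identical for a fixed seed.

Problem sizes in the test suite and acceptance script (50 random
3-region databases of ≥200 ORFs with 1000 query peptides for the search
oracle; the 6-sample cohort for end-to-end recovery) were chosen as the
smallest scales at which every planted failure mode is exercised.

## Numerical and tie-break choices

- All public coordinates are 1-based inclusive plus-strand; BED and
  internal half-open arithmetic are converted at the boundaries.
- Argmax ties break by (chrom, start, end, strand); fragment sort order
  is (peptide, chrom, start, end, strand); both are deterministic.
- Integer-mode counts are stored as floats but asserted integral;
  fractional counts are exact binary fractions of 1/NH sums and compare
  exactly in tests for NH ∈ {2}, within 1e-9 otherwise.
- Strand composition is sign multiplication: region strand × frame
  direction → placement strand; placement strand × chain strand → lifted
  strand.

## Known limitations

- Indels, MNVs and structural variants are not personalized; only SNVs.
- Liftover refuses split intervals rather than projecting partial maps.
- Strandedness of the RNA library is ignored (counting is
  strand-agnostic), matching the underlying counter's default.
- The BLASTP backend's pre-filter hit counts depend on the external
  binary's heuristics and are not reproduced by the exact backend.
- No normalization or differential-expression statistics: raw read
  counts only, and no tumor/normal ratio criterion is imposed.
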
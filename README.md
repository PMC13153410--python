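# hervotrace

Trace query peptides — typically MHC-presented peptides identified by
immunopeptidomic LC-MS/MS — to their candidate genomic origins in human
endogenous retrovirus (HERV) proviruses, and quantify each candidate's
expression from RNA-seq alignments.

## The problem

HERVs make up roughly 8% of the human genome and are normally silenced;
in tumors they can be demethylated, expressed and translated, making them
a promising source of *shared* tumor-specific antigens. Given a short
peptide observed on MHC, the question is: **which HERV locus could have
encoded it, and is that locus actually expressed in the samples at hand?**
The difficulty is the high homology among HERV regions — a 9-mer peptide
can be encoded by dozens of loci, and reads from those loci multi-map.

## The method

1. **Database build.** Every provirus region (sequence + genomic interval
   + strand) is translated in all six reading frames. Maximal stop-free
   stretches between stop codons form the open reading frame (ORF)
   database; exact duplicates within a region are collapsed with their
   genomic placements merged. Because each ORF is generated from the
   region sequence itself, its genomic placement is computed by exact
   frame/offset arithmetic and verified by a translation round-trip:
   for an ORF at amino-acid offset *o* in frame shift *s*, the coding
   interval covers nucleotides `[3o+s, 3o+s+3L)` of the reading
   orientation, mapped through the region's strand to plus-strand
   coordinates. Coordinates can be lifted to other assemblies through
   UCSC chain files (single-block mappings only).
2. **Peptide search (step 1).** A peptide hit is an exact, full-length,
   100%-identity occurrence of the query in an ORF protein — canonical
   backend: exact substring search; a BLASTP backend with the permissive
   short-peptide parameter set (PAM30, word size 3, no compositional
   statistics) is available for compatibility. Each hit maps to a
   **fragment**: the genomic interval of exactly `3 × peptide length`
   bases whose coding-orientation translation is the peptide. Fragments
   are written as GTF. With a per-sample VCF, accumulated SNVs inside
   regions are applied to variant haplotypes and re-translated, so
   peptides created by a sample's mutations are found too (indels are out
   of scope).
3. **Quantification (step 2).** Reads from coordinate-sorted, indexed
   BAMs are counted over fragments (overlap ≥ 1 bp, strand-agnostic, a
   read counts in every fragment it overlaps). Multi-mapped reads are
   excluded by default or counted fractionally at weight 1/NH. One job
   per sample, parallelized, with a task id and per-sample status.
4. **Reporting (step 3).** Counts aggregate to tumor/normal cohort sums;
   per peptide the most-expressed fragment is reported at cohort and
   per-sample level (zero-count cells print `no read`), with
   validation-ready DNA sequence contexts (coding window demarcated, in
   coding orientation) and three heatmap layouts.

## Worked example

The package ships a deterministic simulator that plants known
peptide-coding windows (both strands, nested fragments, a duplicated
multi-mapping locus, an SNV-enabled decoy) into a toy genome and
generates reads with known counts:

```bash
hervotrace simulate --out-dir sim --seed 1
hervotrace build-db --regions-fasta sim/regions.fa --regions-bed sim/regions.bed --out db.json
hervotrace annotate --peptides sim/peptides.fa --db db.json --gtf fragments.gtf
hervotrace quantify --gtf fragments.gtf --manifest sim/manifest.tsv --out counts.tsv --workers 2
hervotrace report --counts counts.tsv --manifest sim/manifest.tsv --gtf fragments.gtf \
    --genome sim/genome.fa --peptides sim/peptides.fa --out-dir report
```

The build logs `built database: 7 regions, 231 ORFs`; annotation finds
`6 peptides -> 6 fragments`. The cohort-level table
(`report/summary_most_expressed_tissue.tsv`) then reads:

```
peptide_id         peptide    herv_region  tumor_reads  total_reads strand
        P1       VILPPQPPK chrA:1101-1127            8           15      +
        P2       AVLLPQPPK chrA:2101-2127            7           17      -
        P3       GILLPQPPK chrB:1101-1127            1           12      +
     PLONG NEAIEQVRAICLRAW chrB:2101-2145           15           30      -
     PNEST       IEQVRAICL chrB:2110-2136            9           20      -
```

Each row names the single most-expressed origin of that peptide over the
whole cohort: e.g. peptide P2 is best explained by the 27-nt window
`chrA:2101-2127` on the minus strand, supported by 17 reads of which 7
come from tumor samples. Every interval satisfies
`end − start + 1 = 3 × peptide length`, and the table's
`validation_ready_sequence` column gives the flanked DNA context in
coding orientation (`UP[CODING]DOWN`) ready for minigene or primer
design. The per-sample table reports the argmax fragment per sample, with
`no read` where a peptide has no expressed candidate in that sample.
All reported counts match the simulator's planted truth exactly.

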
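# Converting raw spreadsheet data to isoscope inputs

The pipeline reads only plain-text formats: aligned FASTA plus a
two-column population map for sequences, and a wide TSV for STR profiles.
Raw data distributed as spreadsheet workbooks (one sheet of mtDNA
haplotypes, one of Y-STR profiles) are converted once, out of band; the
package deliberately has no binary-spreadsheet dependency.

## mtDNA sheet

Two encodings are common; the recipe covers both.

**Full sequences.** If the sheet carries one aligned sequence per row,
export it as TSV with columns `sample_id`, `population`, `sequence` and
run:

```sh
isoscope convert raw_mtdna.tsv --fasta-out mt.fasta --popmap mt.popmap.tsv
```

**Variant lists relative to a reference.** If rows carry positions that
differ from a reference sequence (e.g. `16126C 16294T 073G 263G`), first
materialize full haplotypes: paste the reference segment(s) covering the
sequenced range, apply each listed substitution at its (1-based,
reference-numbered) position, and emit the same three-column TSV as
above. Indels listed as positions with `-` become gap characters in the
alignment; positions outside the sequenced range must not appear. Any
scripting language works; the essential checks are (a) every output
sequence has the same length as the reference segment, and (b) applying
zero variants reproduces the reference exactly. `isoscope validate`
confirms alignment length, alphabet and popmap coverage afterwards.

## Y-STR sheet

Export as TSV with header `sample_id`, `population`, then one column per
locus (e.g. `DYS19 DYS390 DYS391 DYS392 DYS393`), integer repeat counts
in the cells. Use `NA` for a missing call — never 0, which is treated as
a legal allele label. `isoscope validate --str-table profiles.tsv`
checks the result.
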
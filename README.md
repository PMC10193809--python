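# mtaltorf

Discovery of alternative open reading frames (altORFs) hidden inside
annotated mitochondrial genes.

The human mitochondrial genome is a 16.6 kb circle with 37 annotated genes
packed head-to-tail, yet its protein-coding potential is not exhausted by
them: stop-free reading frames nested inside annotated genes — on the same
strand but shifted by 1 or 2 nucleotides, or on the complementary strand —
can encode unannotated micropeptides, as the known rRNA-resident peptides
(Humanin, the SHLPs, MOTS-c) already demonstrate. `mtaltorf` implements the
computational side of that discovery programme for anyone studying small or
alternative proteins in circular genomes:

* **six-frame ORF enumeration on a circular genome**, in *stop-to-stop* mode
  (every maximal codon run free of stops — the mode that surfaces peptides
  starting at non-AUG codons) and *ATG-initiated* mode (including every
  downstream in-frame ATG, which is how an alternative initiation codon
  inside a gene is found);
* **mitochondrial genetic codes**, including the modified vertebrate table
  in which AGA/AGG are read as arginine and only TAA/TAG terminate
  translation;
* **overlap classification** of each ORF against reference annotations:
  `matches_reference`, `sense_frameshift` (with the relative frame offset
  `(orf_start − gene_start) mod 3`), `antisense`, `within_rRNA`,
  `within_tRNA`, `intergenic`, `multi_feature`, and a filter producing the
  *unannotated* candidate set;
* **peptide properties** (average and monoisotopic masses from in-code
  residue tables) and **in-silico tryptic digestion** (≤ 2 missed cleavages,
  ≥ 7 residues, 400–6000 Da by default) producing MS-ready query lists;
* **ortholog conservation shading**: an internal affine-gap global aligner,
  a center-star progressive MSA, and the two-tier column shading used in
  printed ortholog panels (black = conserved in all species, gray = in
  n − 1 of n);
* a **seeded synthetic-genome generator** that plants reference genes and
  altORFs of every kind, with a machine-readable truth table, so the whole
  pipeline is testable without downloading anything.

## Worked example

Simulate a mitogenome-like circle (13 protein-coding genes, 2 rRNAs, 22
tRNAs, a D-loop, and 6 planted altORFs), then run discovery against its
annotations:

```sh
$ mtaltorf simulate --seed 11 --out sim
16662 nt, 38 features, 19 truth records -> sim/

$ mtaltorf scan --genome sim/genome.fasta --gff sim/annotations.gff3 --out run
INFO defaults: code=vertebrate_mito_modified mode=stop_to_stop min_aa=20 (coding nt, stop excluded) start_codons=ATG-only proline_rule=True mass_kind=monoisotopic
INFO scan: 19 ORFs of >= 20 aa (mode=stop_to_stop)
INFO filter_unannotated: 6 of 19 records retained
INFO digest: 65 peptide queries from 6 proteins
6 candidate ORFs -> run/candidates.tsv
```

`candidates.tsv` mirrors the layout of printed candidate tables — peptide,
length, predicted MW in kDa, and a position string in the reporting dialect
(antisense rows keep descending reference coordinates):

```
      id  aa_length  predicted_mw_kda                                    position         category  frame_offset
orf_0001         26               3.3                      intergenic 967 to 1044       intergenic
orf_0002         24               2.6                    Within rrnL 2749 to 2820      within_rRNA
orf_0003         30               3.5   Within nd2 sense, frameshift 5803 to 5892 sense_frameshift             1
orf_0004         99              11.3 Within nd4 sense, frameshift 12095 to 12391 sense_frameshift             2
orf_0005         25               3.1                cox1 anti-sense 7134 to 7060        antisense
orf_0006         24               2.8                cox3 anti-sense 9948 to 9877        antisense
```

The 19 scanned ORFs are the 13 reference genes plus the 6 planted altORFs;
filtering against the annotations removes exactly the reference genes.
`orf_0004` is the planted analogue of a 99-residue peptide frameshifted by
2 nt inside the *nd4*-like gene.  The run directory also contains the
candidate peptides as FASTA, BED and GFF3 intervals, and `digest.tsv` /
`peptide_list.txt` with the tryptic queries (here 65 peptides) ready for
external spectrum matching.

The same pipeline runs on a real genome: point `--genome` at a mitochondrial
reference FASTA (e.g. the human revised Cambridge reference sequence) and
`--gff` at its annotations, optionally passing
`--known-orfs src/mtaltorf/data/known_micropeptides.tsv` (filled in with
coordinates or sequences) to exclude the known micropeptide ORFs from the
unannotated set.

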
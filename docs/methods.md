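# Methods

This note records the models, conventions and numerical choices behind
`mtaltorf`, and what the synthetic fixtures do and do not establish about
real data.

## Genetic codes and translation

Codon tables are total maps from the 64 DNA triplets to one-letter residues
or STOP (`*`), with explicit start and stop sets, validated on load (the
stop set must equal the triplets mapped to STOP; starts are non-empty and
disjoint from stops).  Three named tables ship:

* `standard` — NCBI transl_table 1;
* `vertebrate_mito` — transl_table 2 (TGA→Trp, ATA→Met, AGA/AGG as stops);
* `vertebrate_mito_modified` — transl_table 2 with AGA/AGG reassigned to
  arginine, leaving exactly {TAA, TAG} as stops.  This follows the current
  reading of human mitochondrial termination, in which AGA/AGG are not used
  as stop codons, and is the default for discovery scans.

Base tables are taken from Biopython's codon-table registry and patched;
a user-supplied two-column table can be loaded for other organisms.  DNA
(T) is canonical internally; RNA input is converted on entry.  Both
mitochondrial tables carry starts {ATG, ATA, ATT}, but ATG-initiated
scanning defaults to ATG only, matching the convention of polycistronic
annotation databases; the flag is exposed.  Ambiguity codes are rejected by
default; a lenient mode translates any N-containing triplet as `X` (never a
stop, never a start), which is needed because the human mtDNA reference
contains one placeholder position.

Translation proceeds triplet-by-triplet from position 1, halts before the
first stop (not emitted) and reports how many nucleotides were consumed;
internal-stop policy is thereby the caller's.

## Circular six-frame scanning

A reading frame of a circular genome is a closed cycle of codons: with the
genome length divisible by 3 each strand carries three independent cycles;
otherwise the three phases merge into one cycle visiting every position.
The scanner splits each cycle at its stop codons and emits every maximal
stop-free run of at least `min_aa` codons.  Conventions:

* **Minimum length.** `min_aa = 20` by default, counted in coding codons
  with the stop excluded — i.e. at least 60 coding nucleotides.  Reported
  records carry both `end_no_stop` (last coding base) and
  `nt_length_with_stop` so either end convention can be derived; published
  candidate tables are not internally consistent about whether the stop is
  counted, so both are kept.
* **Coordinates.** 1-based reference positions of coding bases.  Minus-
  strand records report `start > end` (positions descend 5′→3′), the
  dialect of printed "anti-sense a to b" rows; BED (0-based half-open) and
  GFF3 (1-based closed) writers emit standard strand-explicit intervals,
  splitting origin-wrapping records into two parts.
* **Frame labels.** `((start − 1) mod 3) + 1` on the plus strand and
  `−(((L − start) mod 3) + 1)` on the minus strand.  Published frame labels
  for specific candidates use an unstated origin, so no attempt is made to
  reproduce them; all classification relies on *relative* frame offsets,
  which are convention-free.
* **Stop-free cycles.** A frame cycle containing no stop at all is emitted
  once, anchored at the lowest position on the scanned strand's own axis,
  flagged `wraps_origin`, with `has_stop = False`.  Its peptide is one
  rotation of an infinite repeat; tests compare such records up to rotation.
* **ATG mode.** Within each stop-free run, the default is one record at the
  5′-most start codon; `all_downstream_starts` emits one record per
  in-frame start (sharing the run's stop), which is how a downstream
  alternative initiation codon inside an annotated gene is surfaced.

The scanner is checked against a brute-force window oracle (every candidate
start walked forward to its bounding stop, on rotated copies of the
sequence) on hundreds of random genomes, plus rotation-invariance and
strand-duality properties.

## Overlap classification

The host of an ORF is the annotated feature with maximal nucleotide overlap
on the circle; exact ties (and spans covering two features equally) are
reported `multi_feature` with all hosts listed — mitochondrial genes abut
with near-zero spacers, so partial double-overlaps are routine.  For a
same-strand ORF in a protein-coding host, the relative frame offset is
`(orf_start − host_start) mod 3` along the shared 5′→3′ axis (minus-strand
pairs are mapped onto an increasing axis by negation); offset 0 classifies
as `matches_reference`, 1 or 2 as `sense_frameshift`.  Antisense
classification deliberately ignores frame.  ORFs hosted by rRNA or tRNA
genes are `within_rRNA`/`within_tRNA` regardless of strand, and are *kept*
by the unannotated filter — the known mitochondrial micropeptides live
there.  The category enum has no D-loop member, so D-loop-hosted ORFs are
reported `intergenic` with the D-loop recorded as host for traceability.

`filter_unannotated` removes `matches_reference` records and entries
matching a known-micropeptide sidecar by exact peptide string or coordinate
identity.  The sidecar ships with the ten published names (Humanin,
SHLP1–6, MOTS-c, gau, SHMOOSE) and empty sequence/coordinate fields: their
coordinates are build-specific and are the user's to fill in, not
hardcoded.

## Peptide masses

Residue masses are generated in-code from residue elemental compositions:
average masses use the 2009 IUPAC standard atomic weights (C 12.0107,
H 1.00794, N 14.0067, O 15.9994, S 32.065) — the ExPASy convention, which
reproduces vendor-quoted synthetic-peptide MWs to 0.01 Da (the 99-residue
anchor peptide computes to 11 532.065 Da); monoisotopic masses use
most-abundant-isotope masses and are cross-checked against pyteomics in the
tests.  Reported "predicted MW" values are the *average* mass rounded to
one decimal in kDa.  Masses are for unmodified neutral peptides; no PTMs,
isotope envelopes or charge states.

## Tryptic digestion

Cleavage after K or R, never at the C-terminus; the conventional proline
rule (no cleavage before P) defaults on but is configurable, since source
procedures often state only "trypsin".  Peptides spanning up to
`max_miscleavages` (default 2) uncut sites are generated, then filtered by
minimum length (7) and a mass window (400–6000 Da) mimicking experimental
acquisition ranges.  The mass kind for the window defaults to monoisotopic
(the MS search convention); both the proline rule and the mass kind are
echoed in the run log because they are unstated in the procedures being
mirrored.  Digestion consumes peptide FASTA from the scanner, keeping the
modules decoupled, and is verified against brute-force substring
enumeration under the three filters.

## Alignment and conservation shading

The pairwise aligner is a standard three-state affine-gap dynamic
programme; a gap of length k costs `gap_open + (k − 1)·gap_extend` with
defaults (+1, −1, −5, −1).  Tie-breaking is deterministic (substitution,
then gap-in-second, then gap-in-first), so outputs are reproducible.  The
MSA is center-star progressive alignment under "once a gap, always a gap":
the center maximises summed pairwise identity, and each remaining sequence
is merged via its pairwise alignment to the center.  Stop-codon asterisks
in ortholog sequences are a 21st symbol that never matches anything,
itself included.  Column tiers follow the two-tier shading of printed
ortholog panels: `all_conserved` (identical residue in all rows, no gaps),
`near_conserved` (identical in exactly n − 1 of n rows), else `variable`.
Because no gap parameters are published for the panels being emulated, gap
*placement* may legitimately differ from any specific figure; scores are
verified against exhaustive enumeration (short sequences) and Biopython's
`PairwiseAligner` (longer ones).

## Synthetic genomes and the truth table

Plants are embedded stop-bounded in their own frame (a stop codon
immediately before the first coding codon and one after the last), so a
stop-to-stop scan recovers their coordinates exactly.  Nested plants
(sense-frameshifted at a requested offset of 1 or 2, or antisense) are
built by rejection sampling over codon choices until the induced host-frame
codons contain no stop, with bounded retries and an error naming the plant
when a request is infeasible.  Background codons are drawn with an
mtDNA-like base composition (A+T ≈ 55 %) and a configurable per-codon stop
probability in frame 1.

Chance stop-free runs over 20 codons are a statistical certainty in a
16 kb A+T-rich circle — the real human mtDNA carries hundreds, which is
precisely the discovery substrate.  Fixtures that must contain *only* the
planted ORFs above threshold therefore cap the background: any unprotected
run longer than `max_background_orf_aa` (19 in the integration fixture)
receives a stop codon written into it, rewriting only bases that are not
frozen (planted flanking stops, initiator ATGs, previously inserted repair
stops) and never introducing a stop into a protected frame (any planted
ORF's or host gene's).  Plant bodies remain rewritable under those
constraints, and truth peptide sequences are recorded from the final
genome, so the cap cannot invalidate the truth table.  The repair loop
reuses the scanner to find offending runs; recovery tests compare scanner
output against *construction-derived* truth coordinates, so the round trip
remains a meaningful check.

`emulate_mito_layout` arranges 13 protein-coding genes (realistic lengths,
one on the minus strand), 2 rRNAs, 22 tRNAs and a D-loop head-to-tail with
0–3 nt spacers (~16.66 kb, 38 features) and plants six altORFs covering
every kind: sense frameshifts at offsets 1 and 2 (30 and 99 aa — the
latter sized like the known nd4-internal candidate), two antisense ORFs
(24, 25 aa), one rRNA-resident (24 aa) and one D-loop/intergenic (26 aa).
Identical seeds give identical genomes.

**What the fixture does not emulate:** real codon usage and gene content,
transcript punctuation, heteroplasmy, sequencing error, NUMTs, and — by
construction — the natural background of chance ORFs above 20 codons.
Passing the round-trip tests therefore demonstrates correctness of the
scan → classify → filter machinery, not that any particular real-genome
candidate list is complete or correct; on real data the unannotated set is
expected to number in the hundreds, to be triaged by external evidence
(database cross-references, MS spectra), which is out of scope here.

## Pipeline and problem sizes

`run_discovery` chains scan → classify → filter → properties → digest,
writes TSV/FASTA/BED/GFF3/peptide-list outputs plus a run log echoing every
defaulted parameter, removes partial outputs on failure, and is
byte-reproducible for identical inputs.  The test suite runs the scanner
oracle on 100 random genomes up to 300 nt, the digestion oracle on 100
random proteins up to 200 aa (both proline modes), and the full synthetic
round trip on 50 seeds of the ~16.7 kb fixture; these sizes keep the whole
suite under a minute of scanning work while exercising every code path,
and scale linearly for larger inputs.
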
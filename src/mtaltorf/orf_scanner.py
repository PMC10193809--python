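"""Six-frame ORF enumeration on circular (or linear) genomes.

The scanner treats each reading frame of a circular genome as a closed cycle
of codons: when the genome length is a multiple of 3 each strand carries
three independent codon cycles, otherwise the three phases merge into a
single cycle that traverses the circle more than once.  Two discovery modes
are provided:

* ``stop_to_stop`` — every maximal stop-free codon run (no start codon
  required).  This is the mode that surfaces peptides beginning with
  non-methionine residues.
* ``atg_initiated`` — within each stop-free run, ORFs beginning at a start
  codon; by default one record per run (the 5'-most start), optionally one
  per downstream in-frame start, which is how a downstream alternative ATG
  inside an annotated gene is surfaced.

Coordinates are 1-based reference positions of coding bases.  Minus-strand
records report ``start > end_no_stop`` (positions descend 5'→3'), matching
the "anti-sense 9462 to 9177" reporting dialect; the BED/GFF3 writers emit
standard strand-explicit intervals instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

from Bio import SeqIO

from .genetic_code import GeneticCode, normalize_nt, reverse_complement, _check_alphabet

FrameLabel = int  # one of 1, 2, 3, -1, -2, -3


@dataclass(frozen=True)
class CircularGenome:
    """A nucleotide sequence plus its identity and topology."""

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        seq = normalize_nt(self.sequence)
        if not seq:
            raise ValueError("genome sequence is empty")
        _check_alphabet(seq, allow_n=True)
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be 'circular' or 'linear', got {self.topology!r}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass(frozen=True)
class OrfRecord:
    """One detected ORF with reference coordinates of its coding bases."""

    genome_id: str
    strand: str  # '+' or '-'
    frame_label: FrameLabel
    start: int  # 1-based reference position of the first coding base
    end_no_stop: int  # 1-based reference position of the last coding base
    has_stop: bool
    wraps_origin: bool
    mode: str  # 'stop_to_stop' or 'atg_initiated'
    aa_sequence: str

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)

    @property
    def nt_length_with_stop(self) -> int:
        return 3 * self.aa_length + (3 if self.has_stop else 0)


def frame_of(start: int, strand: str, genome_length: int) -> FrameLabel:
    """Deterministic frame label of a coding start position.

    Plus strand: ``((start - 1) mod 3) + 1``; minus strand:
    ``-(((genome_length - start) mod 3) + 1)``.
    """
    if not 1 <= start <= genome_length:
        raise ValueError(f"start {start} out of range 1..{genome_length}")
    if strand == "+":
        return ((start - 1) % 3) + 1
    if strand == "-":
        return -(((genome_length - start) % 3) + 1)
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def _codon_chains(L: int, circular: bool) -> list[tuple[list[int], bool]]:
    """0-based codon start positions of each reading chain on one strand.

    Returns ``(positions, is_cyclic)`` pairs.  On a circle whose length is a
    multiple of 3 there are three cyclic chains; otherwise a single cyclic
    chain visits every position.  Linear genomes have three bounded chains.
    """
    if not circular:
        return [(list(range(f, L - 2, 3)), False) for f in range(3) if f <= L - 3]
    chains: list[tuple[list[int], bool]] = []
    seen: set[int] = set()
    for f in range(3):
        if f in seen:
            continue
        pos, p = [], f
        while p not in seen:
            seen.add(p)
            pos.append(p)
            p = (p + 3) % L
        chains.append((pos, True))
    return chains


def _codon_at(seq: str, p: int, circular: bool) -> str:
    L = len(seq)
    if p + 3 <= L:
        return seq[p : p + 3]
    if not circular:
        raise IndexError("codon past end of linear sequence")
    return (seq + seq[:2])[p : p + 3]


def _aa_of(codon: str, code: GeneticCode) -> str:
    if "N" in codon:
        return "X"
    return code.codon_to_aa[codon]


def _runs_in_chain(
    codons: list[str], cyclic: bool, code: GeneticCode
) -> list[tuple[int, int, bool]]:
    """Maximal stop-free runs as (start_index, length, has_stop) over a chain.

    Indices refer to the chain's codon list; cyclic runs may wrap its end.
    A wholly stop-free cyclic chain yields one run canonically anchored at
    chain index 0 (the caller orders chains by ascending position, so this is
    the lowest reference position).
    """
    n = len(codons)
    stops = [i for i, c in enumerate(codons) if "N" not in c and code.is_stop(c)]
    if not stops:
        return [(0, n, False)]
    runs: list[tuple[int, int, bool]] = []
    if cyclic:
        for k, s in enumerate(stops):
            nxt = stops[(k + 1) % len(stops)]
            length = (nxt - s - 1) % n if len(stops) > 1 else n - 1
            if length:
                runs.append(((s + 1) % n, length, True))
    else:
        bounds = [-1] + stops + [n]
        for k in range(len(bounds) - 1):
            a, b = bounds[k], bounds[k + 1]
            if b - a - 1 > 0:
                runs.append((a + 1, b - a - 1, b < n))
    return runs


def _plus_record(
    genome: CircularGenome,
    chain: list[int],
    codons: list[str],
    idx: int,
    length: int,
    has_stop: bool,
    strand: str,
    mode: str,
    code: GeneticCode,
) -> OrfRecord:
    """Build a record from a chain run; ``strand`` tells how to map coordinates."""
    n = len(chain)
    L = len(genome)
    aa = "".join(_aa_of(codons[(idx + j) % n], code) for j in range(length))
    p0 = chain[idx]  # 0-based position on the scanned (strand-local) sequence
    last = (chain[(idx + length - 1) % n] + 2) % L if genome.is_circular else chain[idx + length - 1] + 2
    if strand == "+":
        start = p0 + 1
        end = last + 1
        wraps = genome.is_circular and (p0 + 3 * length > L)
    else:
        # scanned sequence is the reverse complement; local j -> reference L - j
        start = L - p0
        end = L - last
        wraps = genome.is_circular and (p0 + 3 * length > L)
    return OrfRecord(
        genome_id=genome.id,
        strand=strand,
        frame_label=frame_of(start, strand, L),
        start=start,
        end_no_stop=end,
        has_stop=has_stop,
        wraps_origin=wraps,
        mode=mode,
        aa_sequence=aa,
    )


def _scan_strand(
    genome: CircularGenome, code: GeneticCode, strand: str, mode: str
) -> list[tuple[OrfRecord, list[str], list[int], int, int]]:
    """Raw stop-free runs for one strand, with chain context for ATG trimming."""
    seq = genome.sequence if strand == "+" else reverse_complement(genome.sequence)
    out = []
    for chain, cyclic in _codon_chains(len(seq), genome.is_circular):
        codons = [_codon_at(seq, p, genome.is_circular) for p in chain]
        for idx, length, has_stop in _runs_in_chain(codons, cyclic, code):
            rec = _plus_record(genome, chain, codons, idx, length, has_stop, strand, mode, code)
            if cyclic and not has_stop and length == len(chain):
                # a wholly stop-free frame cycle covers the entire circle
                rec = replace(rec, wraps_origin=True)
            out.append((rec, codons, chain, idx, length))
    return out


def _sort_key(r: OrfRecord):
    return (r.strand, r.frame_label, r.start, r.end_no_stop)


def scan_stop_to_stop(
    genome: CircularGenome, code: GeneticCode, min_aa: int = 20
) -> list[OrfRecord]:
    """Every maximal stop-free codon run of ≥ ``min_aa`` codons, six frames.

    Runs are flanked by stop codons (or sequence ends on a linear genome);
    a wholly stop-free circular frame cycle is emitted once, anchored at its
    lowest reference position and flagged ``wraps_origin``.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if len(genome) < 3:
        raise ValueError("genome shorter than 3 nt")
    records = [
        rec
        for strand in "+-"
        for rec, *_ in _scan_strand(genome, code, strand, "stop_to_stop")
        if rec.aa_length >= min_aa
    ]
    return sorted(records, key=_sort_key)


def scan_atg_initiated(
    genome: CircularGenome,
    code: GeneticCode,
    min_aa: int = 20,
    all_downstream_starts: bool = False,
    atg_only: bool = True,
) -> list[OrfRecord]:
    """ORFs beginning at a start codon within each stop-free run.

    By default only the 5'-most start of each run is reported and the start
    set is {ATG}; ``atg_only=False`` uses the code's full start set and
    ``all_downstream_starts`` emits one record per in-frame start, all
    sharing the run's end.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if len(genome) < 3:
        raise ValueError("genome shorter than 3 nt")
    starts = {"ATG"} if atg_only else set(code.start_codons)
    L = len(genome)
    records: list[OrfRecord] = []
    for strand in "+-":
        for rec, codons, chain, idx, length in _scan_strand(
            genome, code, strand, "atg_initiated"
        ):
            n = len(chain)
            for j in range(length):
                if codons[(idx + j) % n] not in starts:
                    continue
                sub_len = length - j
                if sub_len >= min_aa:
                    p0 = chain[(idx + j) % n]
                    start = p0 + 1 if strand == "+" else L - p0
                    records.append(
                        replace(
                            rec,
                            start=start,
                            end_no_stop=rec.end_no_stop,
                            frame_label=frame_of(start, strand, L),
                            wraps_origin=genome.is_circular and (p0 + 3 * sub_len > L),
                            aa_sequence=rec.aa_sequence[j:],
                        )
                    )
                if not all_downstream_starts:
                    break
    return sorted(records, key=_sort_key)


def orf_nt_sequence(genome: CircularGenome, rec: OrfRecord) -> str:
    """The coding nucleotides of ``rec`` read 5'→3' (round-trip support)."""
    L = len(genome)
    if rec.strand == "+":
        p0 = rec.start - 1
        seq = genome.sequence
    else:
        p0 = L - rec.start
        seq = reverse_complement(genome.sequence)
    span = 3 * rec.aa_length
    if p0 + span <= L:
        return seq[p0 : p0 + span]
    if not genome.is_circular:
        raise ValueError("record extends past the end of a linear genome")
    reps = seq * (2 + span // L)
    return reps[p0 : p0 + span]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path, topology: str = "circular") -> CircularGenome:
    """Read a single-record genome FASTA; multi-record files are rejected."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected exactly one FASTA record, found {len(records)}"
        )
    return CircularGenome(records[0].id, str(records[0].seq), topology)


def write_peptides_fasta(records: list[OrfRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(records, 1):
            fh.write(
                f">orf_{i:04d} {r.genome_id} strand={r.strand} frame={r.frame_label} "
                f"start={r.start} end={r.end_no_stop} mode={r.mode}\n{r.aa_sequence}\n"
            )


def _linear_spans(rec: OrfRecord, L: int) -> list[tuple[int, int]]:
    """Ascending 1-based closed intervals covered by the coding bases."""
    lo, hi = (rec.start, rec.end_no_stop) if rec.strand == "+" else (rec.end_no_stop, rec.start)
    if not rec.wraps_origin:
        return [(lo, hi)]
    # wraps origin: covered positions are lo..L plus 1..hi (hi < lo here)
    return [(lo, L), (1, hi)]


def write_bed(records: list[OrfRecord], path: str | Path, genome_length: int) -> None:
    """0-based half-open BED; origin-wrapping records are split into two lines."""
    with open(path, "w") as fh:
        for i, r in enumerate(records, 1):
            for a, b in _linear_spans(r, genome_length):
                fh.write(
                    f"{r.genome_id}\t{a - 1}\t{b}\torf_{i:04d}\t{r.aa_length}\t{r.strand}\n"
                )


def write_gff3(records: list[OrfRecord], path: str | Path, genome_length: int) -> None:
    """1-based closed GFF3 ORF features; wrapping records split into two parts."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, r in enumerate(records, 1):
            attrs = (
                f"ID=orf_{i:04d};mode={r.mode};frame={r.frame_label};"
                f"aa_length={r.aa_length};wraps_origin={str(r.wraps_origin).lower()}"
            )
            for a, b in _linear_spans(r, genome_length):
                fh.write(
                    f"{r.genome_id}\tmtaltorf\tORF\t{a}\t{b}\t.\t{r.strand}\t0\t{attrs}\n"
                )
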
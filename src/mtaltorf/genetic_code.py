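"""Codon translation tables and strand-aware translation.

Vertebrate mitochondria read several codons differently from the universal
code (TGA→Trp, ATA→Met, and — conventionally — AGA/AGG as stops).  Recent
re-examinations of human mitochondrial translation indicate that AGA and AGG
are in fact decoded as arginine and that only TAA/TAG terminate translation;
the ``vertebrate_mito_modified`` table encodes that reading and is the
default for mitochondrial ORF discovery in this package.

DNA (T, not U) is the canonical internal alphabet; RNA input is converted on
entry.  The one-letter symbol ``*`` denotes STOP in ``codon_to_aa``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable as _BioCodonTable

STOP = "*"
DNA_BASES = "ACGT"
CODONS = tuple("".join(c) for c in itertools.product(DNA_BASES, repeat=3))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Valid arguments to :func:`load_code`.
KNOWN_CODES = ("standard", "vertebrate_mito", "vertebrate_mito_modified")


@dataclass(frozen=True)
class GeneticCode:
    """A total 64-codon translation table with explicit start/stop sets."""

    name: str
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(CODONS):
            missing = set(CODONS) - set(self.codon_to_aa)
            extra = set(self.codon_to_aa) - set(CODONS)
            raise ValueError(
                f"codon table must have exactly the 64 DNA triplets; "
                f"missing={sorted(missing)!r} extra={sorted(extra)!r}"
            )
        derived_stops = frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)
        if self.stop_codons and frozenset(self.stop_codons) != derived_stops:
            raise ValueError(
                f"stop_codons {sorted(self.stop_codons)} disagree with triplets "
                f"mapped to STOP {sorted(derived_stops)}"
            )
        object.__setattr__(self, "stop_codons", derived_stops)
        starts = frozenset(self.start_codons)
        if not starts:
            raise ValueError("start_codons must be non-empty")
        if starts & derived_stops:
            raise ValueError("start_codons and stop_codons must be disjoint")
        object.__setattr__(self, "start_codons", starts)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons


def _table_from_ncbi(table_id: int) -> dict[str, str]:
    bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(bio.forward_table)
    for c in bio.stop_codons:
        mapping[c] = STOP
    return {c: mapping[c] for c in CODONS}


def load_code(name: str) -> GeneticCode:
    """Return a named :class:`GeneticCode`.

    ``standard`` is NCBI transl_table 1; ``vertebrate_mito`` is transl_table 2
    (AGA/AGG stops); ``vertebrate_mito_modified`` is transl_table 2 with
    AGA/AGG reassigned to arginine, so its stop set is exactly {TAA, TAG}.
    Both mitochondrial tables carry start codons {ATG, ATA, ATT}; scanning
    code may restrict to ATG via its own flag.
    """
    if name == "standard":
        return GeneticCode("standard", _table_from_ncbi(1), frozenset({"ATG"}))
    if name == "vertebrate_mito":
        return GeneticCode(
            "vertebrate_mito", _table_from_ncbi(2), frozenset({"ATG", "ATA", "ATT"})
        )
    if name == "vertebrate_mito_modified":
        table = _table_from_ncbi(2)
        table["AGA"] = "R"
        table["AGG"] = "R"
        return GeneticCode(
            "vertebrate_mito_modified", table, frozenset({"ATG", "ATA", "ATT"})
        )
    raise ValueError(f"unknown genetic code {name!r}; valid names: {KNOWN_CODES}")


def load_code_from_table(name: str, text: str, start_codons: set[str] | None = None) -> GeneticCode:
    """Load a user-supplied code from a two-column codon↔aa text table.

    Lines are ``CODON<ws>AA`` with ``*`` for stop; ``#`` comments and blank
    lines ignored.  U is accepted and converted to T.
    """
    mapping: dict[str, str] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2 or len(parts[0]) != 3 or len(parts[1]) != 1:
            raise ValueError(f"line {ln}: expected 'CODON AA', got {line!r}")
        mapping[normalize_nt(parts[0])] = parts[1].upper()
    return GeneticCode(name, mapping, frozenset(start_codons or {"ATG"}))


def normalize_nt(nt: str) -> str:
    """Uppercase and convert RNA (U) to the canonical DNA alphabet."""
    return nt.upper().replace("U", "T")


def _check_alphabet(nt: str, allow_n: bool = False) -> None:
    allowed = set(DNA_BASES) | ({"N"} if allow_n else set())
    for i, ch in enumerate(nt):
        if ch not in allowed:
            raise ValueError(f"invalid nucleotide {ch!r} at position {i + 1}")


def reverse_complement(nt: str) -> str:
    """Watson–Crick reverse complement (involutive); N maps to N."""
    nt = normalize_nt(nt)
    _check_alphabet(nt, allow_n=True)
    return nt.translate(_COMPLEMENT)[::-1]


def translate(
    nt: str,
    code: GeneticCode,
    trim_incomplete: bool = False,
    lenient: bool = False,
) -> tuple[str, int]:
    """Translate consecutive triplets from position 1, halting before a stop.

    Returns ``(aa_sequence, nt_consumed)`` where ``nt_consumed`` counts the
    translated coding bases (the stop codon, if met, is not consumed and not
    emitted).  Trailing 1–2 nt raise unless ``trim_incomplete``.  With
    ``lenient``, any triplet containing N translates as ``X`` (and is not a
    stop); otherwise N is rejected like any invalid character.
    """
    nt = normalize_nt(nt)
    _check_alphabet(nt, allow_n=lenient)
    if len(nt) % 3 and not trim_incomplete:
        raise ValueError(
            f"length {len(nt)} is not a multiple of 3 (pass trim_incomplete to drop the tail)"
        )
    aa = []
    consumed = 0
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            aa.append("X")
        else:
            sym = code.codon_to_aa[codon]
            if sym == STOP:
                break
            aa.append(sym)
        consumed += 3
    return "".join(aa), consumed
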
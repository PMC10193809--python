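"""In-silico tryptic digestion producing MS-ready peptide query lists.

Trypsin cuts after K or R; with the conventional proline rule (default on) a
site followed by P is suppressed.  Peptides spanning up to
``max_miscleavages`` uncut internal sites are generated and then filtered by
minimum length and a mass window — the defaults (≤2 miscleavages, ≥7
residues, 400–6000 Da, monoisotopic) mimic common experimental acquisition
ranges for spectrum-matching queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .protein_properties import average_mass, monoisotopic_mass


@dataclass(frozen=True)
class DigestParams:
    max_miscleavages: int = 2
    min_len: int = 7
    mass_min: float = 400.0
    mass_max: float = 6000.0
    proline_rule: bool = True
    mass_kind: str = "monoisotopic"

    def __post_init__(self) -> None:
        if not 0 <= self.max_miscleavages <= 5:
            raise ValueError("max_miscleavages must be in 0..5")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.mass_min >= self.mass_max:
            raise ValueError("mass_min must be < mass_max")
        if self.mass_kind not in ("monoisotopic", "average"):
            raise ValueError("mass_kind must be 'monoisotopic' or 'average'")


@dataclass(frozen=True)
class PeptideQuery:
    parent_id: str
    aa_sequence: str
    start_in_parent: int  # 1-based residue position
    miscleavages: int
    mass: float


def cleavage_sites(aa: str, proline_rule: bool = True) -> list[int]:
    """1-based positions after which trypsin cleaves.

    Position ``i`` is a site when residue ``i`` is K or R, residue ``i+1``
    exists (the C-terminus is never a site), and — under the proline rule —
    residue ``i+1`` is not P.
    """
    sites = []
    for i in range(1, len(aa)):
        if aa[i - 1] in "KR" and not (proline_rule and aa[i] == "P"):
            sites.append(i)
    return sites


def digest(aa: str, params: DigestParams = DigestParams(), parent_id: str = "protein") -> list[PeptideQuery]:
    """All tryptic peptides with ≤ ``max_miscleavages``, length/mass filtered.

    Deterministic order: by start position, then length.
    """
    massfn = monoisotopic_mass if params.mass_kind == "monoisotopic" else average_mass
    bounds = [0] + cleavage_sites(aa, params.proline_rule) + [len(aa)]
    out: list[PeptideQuery] = []
    for i in range(len(bounds) - 1):
        for m in range(params.max_miscleavages + 1):
            j = i + m + 1
            if j >= len(bounds):
                break
            pep = aa[bounds[i] : bounds[j]]
            if len(pep) < params.min_len:
                continue
            mass = massfn(pep)
            if not params.mass_min <= mass <= params.mass_max:
                continue
            out.append(PeptideQuery(parent_id, pep, bounds[i] + 1, m, mass))
    return sorted(out, key=lambda q: (q.start_in_parent, len(q.aa_sequence)))


def digest_many(
    proteins: dict[str, str], params: DigestParams = DigestParams()
) -> list[PeptideQuery]:
    """Digest a named protein collection, concatenating per-parent results."""
    out: list[PeptideQuery] = []
    for pid, seq in proteins.items():
        out.extend(digest(seq, params, parent_id=pid))
    return out


def write_queries_tsv(queries: list[PeptideQuery], path) -> None:
    with open(path, "w") as fh:
        fh.write("parent\tsequence\tstart\tmiscleavages\tmass\n")
        for q in queries:
            fh.write(
                f"{q.parent_id}\t{q.aa_sequence}\t{q.start_in_parent}\t"
                f"{q.miscleavages}\t{q.mass:.4f}\n"
            )


def write_peptide_list(queries: list[PeptideQuery], path) -> None:
    """Plain peptide list, one sequence per line, deduplicated, sorted."""
    with open(path, "w") as fh:
        for seq in sorted({q.aa_sequence for q in queries}):
            fh.write(seq + "\n")
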
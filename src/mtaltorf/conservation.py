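"""Ortholog peptide alignment and two-tier conservation shading.

A small internal aligner (global pairwise, affine gaps, Gotoh recursion)
feeds a center-star progressive multiple alignment under the classic "once a
gap, always a gap" merge.  Columns are then shaded in two tiers, as in
printed ortholog panels: *all_conserved* (every sequence shows the same
residue, no gaps — black background) and *near_conserved* (identical in
exactly n−1 of n sequences — gray background).

Ortholog peptides read through a stop codon are conventionally written with
``*``; it is accepted as a 21st symbol that never matches anything,
including another ``*``.  Scoring defaults (match +1, mismatch −1, gap open
−5, gap extend −1; a length-k gap costs open + (k−1)·extend) are deliberate
simple defaults — no parameterisation of the original panel is claimed, so
gap placement may differ legitimately from published figures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

GAP = "-"
_VALID = set("ACDEFGHIKLMNPQRSTVWY*")


@dataclass(frozen=True)
class ConservationColumn:
    column_index: int  # 0-based
    residues: tuple[str, ...]
    tier: str  # all_conserved | near_conserved | variable


@dataclass(frozen=True)
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def s(self, x: str, y: str) -> float:
        # '*' never matches anything, itself included
        return self.match if x == y and x != "*" else self.mismatch


def _check_peptide(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what}: empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{what}: invalid residues {sorted(bad)!r}")


def global_align(
    a: str, b: str, scoring: AlignScoring = AlignScoring()
) -> tuple[str, str, float]:
    """Optimal global alignment of two peptides under affine gap scoring.

    Returns ``(aligned_a, aligned_b, score)``.  Ties are broken
    deterministically: prefer the diagonal (substitution) move, then a gap
    in ``b`` (consume from ``a``), then a gap in ``a``.
    """
    _check_peptide(a, "a")
    _check_peptide(b, "b")
    n, m = len(a), len(b)
    NEG = float("-inf")
    go, ge = scoring.gap_open, scoring.gap_extend
    # state 0 (M): a[i] aligned to b[j]; 1 (X): gap in b, a consumed;
    # 2 (Y): gap in a.  ptr[s][i][j] = predecessor state, preference M>X>Y.
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    ptr = [[[0] * (m + 1) for _ in range(n + 1)] for _ in range(3)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + (i - 1) * ge
        ptr[1][i][0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0][j] = go + (j - 1) * ge
        ptr[2][0][j] = 0 if j == 1 else 2

    def _argmax3(vals: tuple[float, float, float]) -> int:
        best = max(vals)
        return vals.index(best)  # first index wins: M before X before Y

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            cand = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            k = _argmax3(cand)
            M[i][j] = cand[k] + scoring.s(ai, b[j - 1])
            ptr[0][i][j] = k
            cand = (M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            k = _argmax3(cand)
            X[i][j] = cand[k]
            ptr[1][i][j] = k
            cand = (M[i][j - 1] + go, X[i][j - 1] + go, Y[i][j - 1] + ge)
            k = _argmax3(cand)
            Y[i][j] = cand[k]
            ptr[2][i][j] = k
    finals = (M[n][m], X[n][m], Y[n][m])
    state = _argmax3(finals)
    score = finals[state]
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = ptr[state][i][j]
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
        state = prev
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Identities over alignment length; '*' never counts as identical."""
    same = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x not in (GAP, "*")
    )
    return same / len(aligned_a) if aligned_a else 0.0


def progressive_msa(
    seqs: list[str], scoring: AlignScoring = AlignScoring()
) -> list[str]:
    """Center-star progressive multiple alignment, "once a gap always a gap".

    The center is the sequence with the highest summed pairwise identity to
    the others (first on ties); every other sequence is aligned to the
    center and merged by inserting shared gap columns into all rows.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa needs at least 2 sequences")
    for k, s in enumerate(seqs):
        _check_peptide(s, f"sequence {k}")
    n = len(seqs)
    ident = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            aa, bb, _ = global_align(seqs[i], seqs[j], scoring)
            ident[i][j] = ident[j][i] = percent_identity(aa, bb)
    center = max(range(n), key=lambda i: (sum(ident[i]), -i))
    # master alignment keyed to the center's residues
    master = [seqs[center]]  # row 0 = center
    order = [center]
    # guide order: decreasing identity to the center (stable on ties)
    others = sorted(
        (k for k in range(n) if k != center), key=lambda k: (-ident[center][k], k)
    )
    for k in others:
        al_center, al_new, _ = global_align(_ungap(master[0]), seqs[k], scoring)
        master = _merge(master, al_center, al_new)
        order.append(k)
    # restore the caller's row order
    rows = [None] * n
    for row, k in zip(master, order):
        rows[k] = row
    return rows  # type: ignore[return-value]


def _ungap(s: str) -> str:
    return s.replace(GAP, "")


def _merge(master: list[str], al_center: str, al_new: str) -> list[str]:
    """Merge a center↔new pairwise alignment into the master alignment."""
    merged = [[] for _ in range(len(master) + 1)]
    mi = 0  # column index into master
    width = len(master[0])
    for c_res, n_res in zip(al_center, al_new):
        if c_res == GAP:
            # a brand-new gap column relative to the center
            for r in range(len(master)):
                merged[r].append(GAP)
            merged[-1].append(n_res)
        else:
            # advance master to the column holding this center residue,
            # copying any master gap columns (gaps already in the center)
            while mi < width and master[0][mi] == GAP:
                for r in range(len(master)):
                    merged[r].append(master[r][mi])
                merged[-1].append(GAP)
                mi += 1
            for r in range(len(master)):
                merged[r].append(master[r][mi])
            merged[-1].append(n_res)
            mi += 1
    while mi < width:  # trailing center-gap columns
        for r in range(len(master)):
            merged[r].append(master[r][mi])
        merged[-1].append(GAP)
        mi += 1
    return ["".join(row) for row in merged]


def conservation_tiers(msa: list[str]) -> tuple[list[ConservationColumn], float]:
    """Per-column two-tier shading and the percent of all-conserved columns."""
    if len(msa) < 2:
        raise ValueError("need at least 2 aligned sequences")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment: rows differ in length")
    cols: list[ConservationColumn] = []
    n = len(msa)
    n_all = 0
    for c in range(width):
        residues = tuple(row[c] for row in msa)
        counts: dict[str, int] = {}
        for r in residues:
            if r not in (GAP, "*"):
                counts[r] = counts.get(r, 0) + 1
        best = max(counts.values(), default=0)
        if best == n:
            tier = "all_conserved"
            n_all += 1
        elif best == n - 1:
            tier = "near_conserved"
        else:
            tier = "variable"
        cols.append(ConservationColumn(c, residues, tier))
    return cols, 100.0 * n_all / width if width else 0.0


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_peptides_fasta(path: str | Path) -> dict[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return {r.id: str(r.seq).upper() for r in records}


def write_alignment_fasta(names: list[str], msa: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(names, msa):
            fh.write(f">{name}\n{row}\n")


def write_tiers_tsv(cols: list[ConservationColumn], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tresidues\ttier\n")
        for c in cols:
            fh.write(f"{c.column_index + 1}\t{''.join(c.residues)}\t{c.tier}\n")


def shaded_text(names: list[str], msa: list[str]) -> str:
    """Plain-text shading: '#' under all-conserved, '+' under near-conserved."""
    cols, _ = conservation_tiers(msa)
    marks = "".join(
        "#" if c.tier == "all_conserved" else "+" if c.tier == "near_conserved" else " "
        for c in cols
    )
    pad = max(len(n) for n in names) + 2
    lines = [f"{n:<{pad}}{row}" for n, row in zip(names, msa)]
    lines.append(" " * pad + marks)
    return "\n".join(lines)
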
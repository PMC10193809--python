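"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's run-splitting, digestion and
dynamic-programming code paths: ORFs are found by checking every
(start, length) window against the stop layout; digestion peptides by
enumerating every substring against the three filters; alignment scores by
exhaustive enumeration of all monotone alignments.
"""

from __future__ import annotations

from mtaltorf.genetic_code import GeneticCode, reverse_complement
from mtaltorf.protein_properties import average_mass, monoisotopic_mass


def _ref_coords(strand: str, p0: int, m: int, L: int) -> tuple[int, int]:
    last = (p0 + 3 * m - 1) % L
    if strand == "+":
        return p0 + 1, last + 1
    return L - p0, L - last


def orf_windows_stop_to_stop(genome, code: GeneticCode, min_aa: int) -> set[tuple]:
    """All maximal stop-free runs, found by window checking.

    Returns tuples (strand, start, end, has_stop, wraps_origin, aa).
    Circular genomes must have length divisible by 3 (three clean codon
    cycles per strand); linear genomes may have any length.
    """
    L = len(genome.sequence)
    out: set[tuple] = set()
    for strand in "+-":
        seq = genome.sequence if strand == "+" else reverse_complement(genome.sequence)
        ext = seq + seq[:2] if genome.is_circular else seq
        if genome.is_circular:
            assert L % 3 == 0, "oracle handles circular genomes with L % 3 == 0"
        for f in range(3):
            positions = list(range(f, L - 2, 3)) if not genome.is_circular else list(range(f, L, 3))
            codons = [ext[p : p + 3] for p in positions]
            stops = [code.is_stop(c) for c in codons]
            n = len(codons)
            if n == 0:
                continue
            if genome.is_circular and not any(stops):
                aa = "".join(code.codon_to_aa[c] for c in codons)
                start, end = _ref_coords(strand, f, n, L)
                out.add((strand, start, end, False, True, aa))
                continue
            for i in range(n):
                if genome.is_circular:
                    if not stops[(i - 1) % n]:
                        continue
                else:
                    if not (i == 0 or stops[i - 1]):
                        continue
                # walk forward from this candidate start to the bounding stop
                m = 0
                while m < n:
                    k = (i + m) % n if genome.is_circular else i + m
                    if k >= n or stops[k]:
                        break
                    m += 1
                has_stop = (
                    stops[(i + m) % n] if genome.is_circular else (i + m < n)
                )
                if m < min_aa or m == 0:
                    continue
                wraps = genome.is_circular and positions[i] + 3 * m > L
                aa = "".join(code.codon_to_aa[codons[(i + k) % n]] for k in range(m))
                start, end = _ref_coords(strand, positions[i], m, L)
                out.add((strand, start, end, has_stop, wraps, aa))
    return out


def orf_windows_atg(
    genome, code: GeneticCode, min_aa: int, all_downstream: bool
) -> set[tuple]:
    """ATG-initiated ORFs derived from the stop-to-stop window oracle."""
    L = len(genome.sequence)
    out: set[tuple] = set()
    for strand, start, end, has_stop, _wraps, aa in orf_windows_stop_to_stop(
        genome, code, 1
    ):
        seq = genome.sequence if strand == "+" else reverse_complement(genome.sequence)
        ext = seq + seq + seq
        p0 = start - 1 if strand == "+" else L - start
        hits = 0
        for j in range(len(aa)):
            codon = ext[p0 + 3 * j : p0 + 3 * j + 3]
            if codon != "ATG":
                continue
            hits += 1
            if len(aa) - j >= min_aa:
                q0 = (p0 + 3 * j) % L
                s, e = _ref_coords(strand, q0, len(aa) - j, L)
                wraps = genome.is_circular and q0 + 3 * (len(aa) - j) > L
                out.add((strand, s, e, has_stop, wraps, aa[j:]))
            if not all_downstream:
                break
    return out


def records_as_tuples(records) -> set[tuple]:
    return {
        (r.strand, r.start, r.end_no_stop, r.has_stop, r.wraps_origin, r.aa_sequence)
        for r in records
    }


def digest_windows(aa: str, params) -> list[tuple[int, str, int]]:
    """Every substring passing the tryptic filters, as (start, seq, miscleavages)."""
    sites = set()
    for i in range(1, len(aa)):
        if aa[i - 1] in "KR" and not (params.proline_rule and aa[i] == "P"):
            sites.add(i)
    boundaries = sites | {0, len(aa)}
    massfn = monoisotopic_mass if params.mass_kind == "monoisotopic" else average_mass
    out = []
    for i in range(len(aa)):
        for j in range(i + 1, len(aa) + 1):
            if i not in boundaries or j not in boundaries:
                continue
            internal = sum(1 for s in sites if i < s < j)
            if internal > params.max_miscleavages:
                continue
            pep = aa[i:j]
            if len(pep) < params.min_len:
                continue
            if not params.mass_min <= massfn(pep) <= params.mass_max:
                continue
            out.append((i + 1, pep, internal))
    return sorted(out)


def align_enumerate(a: str, b: str, scoring) -> float:
    """Best affine-gap global alignment score by exhaustive enumeration."""
    best = [float("-inf")]

    def step(i: int, j: int, score: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            step(i + 1, j + 1, score + scoring.s(a[i], b[j]), "M")
        if i < len(a):
            cost = scoring.gap_extend if prev == "X" else scoring.gap_open
            step(i + 1, j, score + cost, "X")
        if j < len(b):
            cost = scoring.gap_extend if prev == "Y" else scoring.gap_open
            step(i, j + 1, score + cost, "Y")

    step(0, 0, 0.0, "M")
    return best[0]
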
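"""Seeded generator of circular genomes with planted reference genes and
planted alternative ORFs, plus a machine-readable truth table.

Every planted ORF is constructed stop-bounded in its own frame: a stop
codon immediately 5' of the first coding codon and another immediately 3'
of the last, so a stop-to-stop scan recovers its coordinates exactly.
Overlapping plants (sense frameshifts inside a host gene, antisense ORFs
under an intact host) are built by rejection sampling over codon choices:
codons for the plant's frame are drawn until the induced codons of the
host's frame contain no stop (bounded retries, then an error naming the
plant).

Chance background ORFs are a fact of A+T-rich sequence — the real
mitochondrial genome carries hundreds of unannotated stop-free runs over 20
codons, which is precisely the discovery substrate.  For fixtures that must
contain *only* the planted ORFs above a length threshold, the generator can
cap background runs: any stop-free run longer than ``max_background_orf_aa``
codons in any of the six frames, outside protected plant footprints, gets a
stop codon written into its middle (never altering a planted ORF, a gene's
start/stop, or a host gene's frame).  ``emulate_mito_layout`` uses this cap
so that filtering the scan against its annotations returns exactly the
planted alternative ORFs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .annotation_overlap import GeneAnnotation
from .genetic_code import GeneticCode, reverse_complement
from .orf_scanner import CircularGenome, OrfRecord, frame_of, scan_stop_to_stop

_MAX_TRIES = 500


@dataclass(frozen=True)
class PlantSpec:
    """Request for one planted ORF.

    ``kind`` is one of reference_gene, sense_frameshift, antisense,
    rna_resident, intergenic.  ``host`` names the reference gene (for
    sense_frameshift/antisense) or noncoding feature (rna_resident) the
    plant must sit inside; ``frame_offset_requested`` (1 or 2) applies to
    sense_frameshift only.  ``start_hint`` pins the 1-based position of the
    first coding base (reference genes only); otherwise placement is random.
    """

    kind: str
    name: str
    host: str | None = None
    frame_offset_requested: int | None = None
    aa_length: int = 25
    start_hint: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        kinds = ("reference_gene", "sense_frameshift", "antisense", "rna_resident", "intergenic")
        if self.kind not in kinds:
            raise ValueError(f"unknown plant kind {self.kind!r}")
        if self.aa_length < 1:
            raise ValueError("aa_length must be >= 1")
        if self.kind == "sense_frameshift":
            if self.host is None or self.frame_offset_requested not in (1, 2):
                raise ValueError(
                    f"{self.name}: sense_frameshift requires host and frame_offset_requested in {{1,2}}"
                )
        if self.kind == "antisense" and self.host is None:
            raise ValueError(f"{self.name}: antisense requires a host")


@dataclass(frozen=True)
class TruthRecord:
    name: str
    kind: str
    start: int  # 1-based first coding base (5' on its strand)
    end: int  # 1-based last coding base
    strand: str
    frame_label: int
    aa_sequence: str
    expected_category: str
    host: str | None = None
    frame_offset: int | None = None


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def planted_alt(self) -> list[TruthRecord]:
        return [r for r in self.records if r.kind != "reference_gene"]


class PlantError(ValueError):
    pass


def _rand_codon(rng, code: GeneticCode, stop: bool, at: float) -> str:
    """One random codon, stop or non-stop, with mtDNA-like base composition."""
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])  # A C G T
    bases = "ACGT"
    if stop:
        stops = sorted(code.stop_codons)
        return stops[rng.integers(len(stops))]
    for _ in range(_MAX_TRIES):
        codon = "".join(bases[k] for k in rng.choice(4, size=3, p=p))
        if not code.is_stop(codon):
            return codon
    raise PlantError("could not draw a non-stop codon")


class _GenomeBuilder:
    """Mutable genome under construction, with footprint bookkeeping."""

    def __init__(self, length: int, code: GeneticCode, rng, stop_density: float, at: float):
        if length % 3:
            raise ValueError("genome length must be a multiple of 3")
        if length < 9:
            raise ValueError("genome too short")
        self.L = length
        self.code = code
        self.rng = rng
        self.at = at
        codons = []
        for _ in range(length // 3):
            is_stop = rng.random() < stop_density
            codons.append(_rand_codon(rng, code, is_stop, at))
        self.seq = list("".join(codons))
        self.reserved: list[tuple[int, int]] = []  # 0-based closed intervals
        # 0-based positions that the background cap must never rewrite
        self.frozen: set[int] = set()
        # protected reading frames: (strand, 0-based strand-local coding start, aa_len)
        self.protected: list[tuple[str, int, int, str]] = []  # + name

    # -- low-level helpers ---------------------------------------------------

    def _free(self, a: int, b: int) -> bool:
        return all(not (a <= hi and lo <= b) for lo, hi in self.reserved)

    def reserve(self, a: int, b: int) -> None:
        self.reserved.append((a, b))

    def place(self, footprint: int, hint0: int | None) -> int:
        """Find a 0-based start for a footprint of the given nt length."""
        if hint0 is not None:
            if hint0 + footprint > self.L or not self._free(hint0, hint0 + footprint - 1):
                raise PlantError(f"hinted placement {hint0 + 1} does not fit")
            return hint0
        for _ in range(_MAX_TRIES):
            a = int(self.rng.integers(0, self.L - footprint))
            if self._free(a, a + footprint - 1):
                return a
        raise PlantError("no free placement found")

    def write(self, pos0: int, nt: str, freeze: bool = True) -> None:
        for k, ch in enumerate(nt):
            self.seq[(pos0 + k) % self.L] = ch
        if freeze:
            self.frozen.update((pos0 + k) % self.L for k in range(len(nt)))

    def local_to_ref(self, strand: str, p0: int) -> int:
        """0-based strand-local position -> 1-based reference position."""
        return p0 + 1 if strand == "+" else self.L - p0

    def strand_seq(self, strand: str) -> str:
        s = "".join(self.seq)
        return s if strand == "+" else reverse_complement(s)

    # -- plant constructors --------------------------------------------------

    def plant_simple(self, spec: PlantSpec, pos_hint0: int | None = None) -> TruthRecord:
        """A stop-bounded ORF with no overlap constraint (genes, RNA-resident,
        intergenic plants).  Returns its truth record (category filled later).

        Only the flanking stops and the initiator ATG are frozen; the body
        stays rewritable by the background cap (which may not introduce a
        stop into this plant's frame).  Truth peptide sequences are
        refreshed from the final genome once every plant and cap is in.
        """
        m = spec.aa_length
        footprint = 3 * (m + 2)
        a = self.place(footprint, pos_hint0)
        body = ["ATG"] + [
            _rand_codon(self.rng, self.code, False, self.at) for _ in range(m - 1)
        ]
        nt = (
            _rand_codon(self.rng, self.code, True, self.at)
            + "".join(body)
            + _rand_codon(self.rng, self.code, True, self.at)
        )
        if spec.strand == "-":
            self.write(a, reverse_complement(nt), freeze=False)
        else:
            self.write(a, nt, freeze=False)
        # flanking stops and the ATG stay immutable in genome coordinates
        if spec.strand == "+":
            fixed = list(range(a, a + 6)) + list(range(a + footprint - 3, a + footprint))
        else:
            fixed = list(range(a, a + 3)) + list(range(a + footprint - 6, a + footprint))
        self.frozen.update(p % self.L for p in fixed)
        self.reserve(a, a + footprint - 1)
        if spec.strand == "+":
            coding0 = a + 3
        else:
            # on the minus strand the written segment reads 5'->3' from the
            # right edge; strand-local index of genome position p is L-1-p
            coding0 = self.L - (a + footprint - 3)  # strand-local 0-based
        self.protected.append((spec.strand, coding0, m, spec.name))
        start = self.local_to_ref(spec.strand, coding0)
        end_local = coding0 + 3 * m - 1
        end = self.local_to_ref(spec.strand, end_local)
        aa = self._retranslate(spec.strand, coding0, m)
        return TruthRecord(
            spec.name, spec.kind, start, end, spec.strand,
            frame_of(start, spec.strand, self.L), aa, "", spec.host, None,
        )

    _COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def _strand_base(self, strand: str, q: int) -> str:
        q %= self.L
        if strand == "+":
            return self.seq[q]
        return self._COMP[self.seq[self.L - 1 - q]]

    def _strand_codon(self, strand: str, q: int) -> str:
        return "".join(self._strand_base(strand, q + k) for k in range(3))

    def _retranslate(self, strand: str, coding0: int, m: int) -> str:
        return "".join(
            self.code.codon_to_aa[self._strand_codon(strand, coding0 + 3 * c)]
            for c in range(m)
        )

    def plant_nested(
        self,
        spec: PlantSpec,
        host_rec: TruthRecord,
        host_reserved: list[tuple[int, int]],
    ) -> TruthRecord:
        """Sense-frameshift or antisense plant inside an intact host gene.

        Works in host-local coordinates (0 = first base of the host's ATG on
        the host's strand).  The plant footprint is stop + coding + stop; the
        host frame over the footprint (with one codon of margin) must stay
        stop-free, enforced by rejection sampling.
        """
        m = spec.aa_length
        footprint = 3 * (m + 2)
        host_aa = len(host_rec.aa_sequence)
        host_coding0 = self._host_local0(host_rec)
        lo = 3  # keep the host ATG intact
        hi = 3 * host_aa - 1  # keep the host stop codon intact
        if spec.kind == "sense_frameshift":
            # l = host-local offset of the plant's prefix stop; the coding
            # start l+3 must satisfy (l+3) % 3 == k relative to the host frame
            k = spec.frame_offset_requested
            choices = [l for l in range(lo, hi - footprint + 2) if (l + 3) % 3 == k % 3]
        else:
            choices = list(range(lo, hi - footprint + 2))
        choices = [
            l for l in choices if self._nested_free(l, l + footprint - 1, host_reserved)
        ]
        if not choices:
            raise PlantError(f"{spec.name}: no room inside host {host_rec.name}")
        order = list(self.rng.permutation(len(choices)))
        for ci in order[: min(len(order), 50)]:
            l = choices[ci]
            nt = self._try_nested_fill(spec, host_rec, l, footprint)
            if nt is None:
                continue
            return self._commit_nested(spec, host_rec, host_reserved, l, footprint, nt)
        raise PlantError(
            f"{spec.name}: could not satisfy host-frame constraints after bounded retries"
        )

    def _host_local0(self, host_rec: TruthRecord) -> int:
        """0-based strand-local position of the host's first coding base."""
        if host_rec.strand == "+":
            return host_rec.start - 1
        return self.L - host_rec.start

    def _nested_free(
        self, a: int, b: int, host_reserved: list[tuple[int, int]]
    ) -> bool:
        return all(not (a <= hi and lo <= b) for lo, hi in host_reserved)

    def _try_nested_fill(
        self, spec: PlantSpec, host_rec: TruthRecord, l: int, footprint: int
    ) -> str | None:
        """Rejection-sample plant nt (host-local, host-strand orientation).

        Returns the host-strand nucleotide string of length ``footprint`` to
        write at host-local offset ``l``, or None if retries were exhausted.
        """
        m = spec.aa_length
        for _ in range(60):
            body = ["ATG"] + [
                _rand_codon(self.rng, self.code, False, self.at) for _ in range(m - 1)
            ]
            plant_nt = (
                _rand_codon(self.rng, self.code, True, self.at)
                + "".join(body)
                + _rand_codon(self.rng, self.code, True, self.at)
            )
            host_nt = (
                plant_nt if spec.kind == "sense_frameshift" else reverse_complement(plant_nt)
            )
            if self._host_frame_ok(host_rec, l, host_nt):
                return host_nt
        return None

    def _host_frame_ok(self, host_rec: TruthRecord, l: int, host_nt: str) -> bool:
        """Would writing ``host_nt`` at host-local ``l`` keep the host stop-free?"""
        host_aa = len(host_rec.aa_sequence)
        host0 = self._host_local0(host_rec)
        s = self.strand_seq(host_rec.strand)
        s2 = s + s
        region = list(s2[host0 : host0 + 3 * host_aa])
        for k, ch in enumerate(host_nt):
            region[l + k] = ch
        for c in range(0, 3 * host_aa, 3):
            if self.code.is_stop("".join(region[c : c + 3])):
                return False
        return True

    def _commit_nested(
        self,
        spec: PlantSpec,
        host_rec: TruthRecord,
        host_reserved: list[tuple[int, int]],
        l: int,
        footprint: int,
        host_nt: str,
    ) -> TruthRecord:
        host0 = self._host_local0(host_rec)
        # convert host-local to genome 0-based (host strand orientation)
        if host_rec.strand == "+":
            g0 = (host0 + l) % self.L
            genome_nt = host_nt
        else:
            # strand-local q maps to genome 0-based L-1-q; the block covers
            # strand-local [host0+l, host0+l+fp-1]
            g0 = (self.L - host0 - (l + footprint - 1) - 1) % self.L
            genome_nt = reverse_complement(host_nt)
        self.write(g0, genome_nt, freeze=False)
        host_reserved.append((l, l + footprint - 1))
        m = spec.aa_length
        if spec.kind == "sense_frameshift":
            plant_strand = host_rec.strand
            coding_local = host0 + l + 3  # on the host strand
        else:
            plant_strand = "-" if host_rec.strand == "+" else "+"
            # plant-strand local coordinate of the first coding base:
            # the written block occupies host-strand local [host0+l, host0+l+fp-1],
            # i.e. plant-strand local [L-1-(host0+l+fp-1), L-1-(host0+l)] ...
            # first coding base (after the prefix stop, 5' on plant strand)
            host_block_start_ref = self.local_to_ref(host_rec.strand, host0 + l)
            # reference of plant-strand 5' end of block:
            if plant_strand == "-":
                # block on + strand ref interval [g0+1, g0+footprint] (may wrap)
                plant5_ref = (g0 + footprint - 1) % self.L + 1
            else:
                plant5_ref = g0 + 1
            coding_local = (self.L - plant5_ref if plant_strand == "-" else plant5_ref - 1) + 3
        # freeze the plant's flanking stops and initiator ATG (genome coords)
        if plant_strand == "+":
            fixed = list(range(g0, g0 + 6)) + list(range(g0 + footprint - 3, g0 + footprint))
        else:
            fixed = list(range(g0, g0 + 3)) + list(range(g0 + footprint - 6, g0 + footprint))
        self.frozen.update(p % self.L for p in fixed)
        self.protected.append((plant_strand, coding_local % self.L, m, spec.name))
        start = self.local_to_ref(plant_strand, coding_local % self.L)
        end = self.local_to_ref(plant_strand, (coding_local + 3 * m - 1) % self.L)
        aa = self._retranslate(plant_strand, coding_local % self.L, m)
        category = "sense_frameshift" if spec.kind == "sense_frameshift" else "antisense"
        return TruthRecord(
            spec.name, spec.kind, start, end, plant_strand,
            frame_of(start, plant_strand, self.L), aa, category,
            host_rec.name, spec.frame_offset_requested,
        )

    # -- background ORF cap ----------------------------------------------------

    def cap_background(self, max_aa: int) -> None:
        """Insert stops so no non-planted stop-free run exceeds ``max_aa`` codons."""
        genome = CircularGenome("tmp", "".join(self.seq))
        protected_keys = {
            (strand, self.local_to_ref(strand, p0)) for strand, p0, _, _ in self.protected
        }
        for _pass in range(200):
            changed = False
            recs = scan_stop_to_stop(genome, self.code, min_aa=max_aa + 1)
            for rec in recs:
                if (rec.strand, rec.start) in protected_keys:
                    continue
                if self._break_run(rec):
                    changed = True
            if not changed:
                if not recs or all(
                    (r.strand, r.start) in protected_keys for r in recs
                ):
                    return
                raise PlantError("could not cap a background ORF (all positions frozen)")
            genome = CircularGenome("tmp", "".join(self.seq))
        raise PlantError("background capping did not converge")

    def _break_run(self, rec: OrfRecord) -> bool:
        """Write a stop into the middle of a run without touching frozen nt or
        inducing a stop into any protected frame."""
        L = self.L
        m = rec.aa_length
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        # candidate codon indices, middle outwards; edges last (a stop there
        # merely shortens the run, which a later pass can finish off)
        mid = m // 2
        order = sorted(range(m), key=lambda c: (c in (0, m - 1), abs(c - mid)))
        local0 = rec.start - 1 if rec.strand == "+" else L - rec.start
        for c in order:
            p_local = (local0 + 3 * c) % L
            # genome 0-based position of each codon letter k
            placement = [
                ((p_local + k) % L) if rec.strand == "+" else (L - 1 - (p_local + k) % L)
                for k in range(3)
            ]
            current = self._strand_codon(rec.strand, p_local)
            for stop in sorted(self.code.stop_codons):
                # rewrite only the differing bases — fewer conflicts with
                # frozen positions and with overlapping protected frames
                diffs = [k for k in range(3) if current[k] != stop[k]]
                if not diffs or any(placement[k] in self.frozen for k in diffs):
                    continue
                saved = {placement[k]: self.seq[placement[k]] for k in diffs}
                for k in diffs:
                    self.seq[placement[k]] = (
                        stop[k] if rec.strand == "+" else comp[stop[k]]
                    )
                if self._protected_ok(list(saved)):
                    # freeze the whole repair stop so later repairs keep it
                    self.frozen.update(placement)
                    return True
                for g, ch in saved.items():
                    self.seq[g] = ch
        return False

    def _protected_ok(self, changed: list[int] | None = None) -> bool:
        """No protected frame carries a stop.

        With ``changed`` (genome 0-based positions just rewritten), only the
        protected codons overlapping those positions are checked — the rest
        were stop-free before and are untouched.
        """
        for strand, p0, m, _name in self.protected:
            if changed is None:
                codon_idxs = range(m)
            else:
                idxs = set()
                for g in changed:
                    q = g if strand == "+" else self.L - 1 - g  # strand-local
                    c = (q - p0) // 3
                    if 0 <= c < m:
                        idxs.add(c)
                codon_idxs = sorted(idxs)
            for c in codon_idxs:
                if self.code.is_stop(self._strand_codon(strand, p0 + 3 * c)):
                    return False
        return True


def generate_genome(
    length: int,
    code: GeneticCode,
    plants: list[PlantSpec],
    background_stop_density: float = 0.05,
    seed: int | None = None,
    at_fraction: float = 0.55,
    max_background_orf_aa: int | None = None,
    noncoding_features: list[GeneAnnotation] | None = None,
) -> tuple[CircularGenome, list[GeneAnnotation], TruthTable]:
    """Build a circular genome with planted ORFs and a truth table.

    Reference-gene plants become protein_coding annotations (their CDS span
    includes the stop codon, as real mitochondrial annotations do); nested
    plants are embedded without breaking their hosts.  Identical seeds give
    identical output.  ``max_background_orf_aa`` caps chance stop-free runs
    (see module docstring); None leaves the background untouched.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducible generation")
    rng = np.random.default_rng(seed)
    footprint_total = sum(3 * (p.aa_length + 2) for p in plants)
    if footprint_total > length:
        raise PlantError("total planted footprint exceeds genome length")
    builder = _GenomeBuilder(length, code, rng, background_stop_density, at_fraction)

    annotations: list[GeneAnnotation] = list(noncoding_features or [])
    for feat in annotations:
        # the D-loop is background-like: random plants may land inside it
        if feat.feature_type != "D_loop":
            builder.reserve(feat.start - 1, feat.end - 1)

    truth = TruthTable()
    gene_records: dict[str, TruthRecord] = {}
    host_reserved: dict[str, list[tuple[int, int]]] = {}

    for spec in [p for p in plants if p.kind == "reference_gene"]:
        # start_hint anchors the 1-based position where the footprint
        # (prefix stop + coding + stop) begins
        hint0 = None if spec.start_hint is None else spec.start_hint - 1
        rec = builder.plant_simple(spec, hint0)
        rec = _with_category(rec, "matches_reference", frame_offset=0, host=spec.name)
        gene_records[spec.name] = rec
        host_reserved[spec.name] = []
        annotations.append(_gene_annotation(rec, builder.L))

    for spec in [p for p in plants if p.kind in ("sense_frameshift", "antisense")]:
        if spec.host not in gene_records:
            raise PlantError(f"{spec.name}: host {spec.host!r} is not a planted reference gene")
        rec = builder.plant_nested(spec, gene_records[spec.host], host_reserved[spec.host])
        truth.records.append(rec)

    for spec in [p for p in plants if p.kind == "rna_resident"]:
        host_feats = [a for a in annotations if a.name == spec.host]
        if not host_feats or host_feats[0].feature_type not in ("rRNA", "tRNA"):
            raise PlantError(f"{spec.name}: rna_resident host {spec.host!r} not an RNA feature")
        feat = host_feats[0]
        footprint = 3 * (spec.aa_length + 2)
        if feat.end - feat.start + 1 < footprint:
            raise PlantError(f"{spec.name}: host RNA {feat.name} too short")
        offset = int(rng.integers(0, feat.end - feat.start + 2 - footprint))
        a0 = feat.start - 1 + offset
        builder.reserved.remove((feat.start - 1, feat.end - 1))
        rec = builder.plant_simple(spec, a0)
        builder.reserve(feat.start - 1, feat.end - 1)
        cat = "within_rRNA" if feat.feature_type == "rRNA" else "within_tRNA"
        truth.records.append(_with_category(rec, cat, host=feat.name))

    for spec in [p for p in plants if p.kind == "intergenic"]:
        rec = builder.plant_simple(spec)
        dloop = [
            a
            for a in annotations
            if a.feature_type == "D_loop"
            and a.start <= min(rec.start, rec.end)
            and max(rec.start, rec.end) <= a.end
        ]
        truth.records.append(
            _with_category(rec, "intergenic", host=dloop[0].name if dloop else None)
        )

    if max_background_orf_aa is not None:
        builder.cap_background(max_background_orf_aa)

    # plant bodies may have been rewritten by later plants or the background
    # cap (never their frames' stop-freedom): refresh every truth sequence
    # from the final genome
    truth.records.extend(gene_records.values())
    truth.records = [
        dataclasses.replace(
            rec,
            aa_sequence=builder._retranslate(
                rec.strand,
                rec.start - 1 if rec.strand == "+" else builder.L - rec.start,
                len(rec.aa_sequence),
            ),
        )
        for rec in truth.records
    ]

    genome = CircularGenome(f"synthetic_seed{seed}", "".join(builder.seq))
    return genome, annotations, truth


def _with_category(
    rec: TruthRecord, category: str, frame_offset: int | None = None, host: str | None = None
) -> TruthRecord:
    return TruthRecord(
        rec.name, rec.kind, rec.start, rec.end, rec.strand, rec.frame_label,
        rec.aa_sequence, category, host if host is not None else rec.host,
        frame_offset if frame_offset is not None else rec.frame_offset,
    )


def _gene_annotation(rec: TruthRecord, L: int) -> GeneAnnotation:
    """CDS annotation spanning the coding bases plus the stop codon."""
    if rec.strand == "+":
        return GeneAnnotation(rec.name, "protein_coding", rec.start, rec.end + 3, rec.strand)
    return GeneAnnotation(rec.name, "protein_coding", rec.end - 3, rec.start, rec.strand)


# ---------------------------------------------------------------------------
# the integration fixture
# ---------------------------------------------------------------------------

# (name, aa length) for the 13 protein-coding genes, mtDNA-like sizes;
# "nd6l" sits on the minus strand as nd6 does in the real genome
_GENE_PLAN = [
    ("nd1", 318), ("nd2", 347), ("cox1", 513), ("cox2", 227), ("atp8", 68),
    ("atp6", 226), ("cox3", 261), ("nd3", 115), ("nd4l", 98), ("nd4", 459),
    ("nd5", 603), ("nd6", 174), ("cytb", 380),
]
_RRNA_PLAN = [("rrnS", 954), ("rrnL", 1557)]
_TRNA_LEN = 69
_DLOOP_LEN = 1122


def emulate_mito_layout(
    seed: int, code: GeneticCode | None = None
) -> tuple[CircularGenome, list[GeneAnnotation], TruthTable]:
    """A ~16.5 kb circular fixture shaped like the vertebrate mitogenome.

    13 protein-coding genes, 2 rRNAs, 22 tRNAs and one D-loop packed
    head-to-tail (38 features), plus 6 planted alternative ORFs covering
    every plant kind.  Background runs are capped below 20 codons, so a
    default discovery scan filtered against the annotations returns exactly
    the planted alternative ORFs.
    """
    from .genetic_code import load_code

    code = code or load_code("vertebrate_mito_modified")
    rng = np.random.default_rng(seed)

    # lay features head-to-tail with 0-3 nt spacers
    layout: list[tuple[str, str, int, str]] = []  # name, type, length_nt, strand
    layout.append(("D_loop", "D_loop", _DLOOP_LEN, "+"))
    trna_names = [f"trn{chr(ord('A') + i)}" for i in range(22)]
    ti = iter(trna_names)
    layout.append((next(ti), "tRNA", _TRNA_LEN, "+"))
    layout.append(("rrnS", "rRNA", _RRNA_PLAN[0][1], "+"))
    layout.append((next(ti), "tRNA", _TRNA_LEN, "+"))
    layout.append(("rrnL", "rRNA", _RRNA_PLAN[1][1], "+"))
    layout.append((next(ti), "tRNA", _TRNA_LEN, "+"))
    remaining_trnas = list(ti)
    for gi, (gname, gaa) in enumerate(_GENE_PLAN):
        strand = "-" if gname == "nd6" else "+"
        layout.append((gname, "protein_coding", 3 * (gaa + 2), strand))
        # sprinkle the remaining 19 tRNAs between genes
        n_t = 2 if gi < 6 else 1
        for _ in range(n_t):
            if remaining_trnas:
                t_strand = "-" if len(remaining_trnas) % 5 == 0 else "+"
                layout.append((remaining_trnas.pop(0), "tRNA", _TRNA_LEN, t_strand))

    pos = 1
    noncoding: list[GeneAnnotation] = []
    gene_specs: list[PlantSpec] = []
    for name, ftype, nt_len, strand in layout:
        spacer = int(rng.integers(0, 4))
        pos += spacer
        if ftype == "protein_coding":
            aa = (nt_len // 3) - 2
            gene_specs.append(
                PlantSpec("reference_gene", name, aa_length=aa,
                          start_hint=pos, strand=strand)
            )
        else:
            noncoding.append(GeneAnnotation(name, ftype, pos, pos + nt_len - 1, strand))
        pos += nt_len
    total = pos + 2
    total += (3 - total % 3) % 3

    alt_specs = [
        PlantSpec("sense_frameshift", "alt_nd4_fs2", host="nd4",
                  frame_offset_requested=2, aa_length=99),
        PlantSpec("sense_frameshift", "alt_nd2_fs1", host="nd2",
                  frame_offset_requested=1, aa_length=30),
        PlantSpec("antisense", "alt_cox3_as", host="cox3", aa_length=24),
        PlantSpec("antisense", "alt_cox1_as", host="cox1", aa_length=25),
        PlantSpec("rna_resident", "alt_rrnL_res", host="rrnL", aa_length=24),
        PlantSpec("intergenic", "alt_dloop", aa_length=26),
    ]

    # the intergenic plant goes inside the D-loop span: hint a start there
    genome, annotations, truth = generate_genome(
        total,
        code,
        gene_specs + alt_specs,
        background_stop_density=0.05,
        seed=int(rng.integers(0, 2**31 - 1)),
        max_background_orf_aa=19,
        noncoding_features=noncoding,
    )
    return genome, annotations, truth


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: TruthTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tkind\tstart\tend\tstrand\tframe\taa_sequence\tcategory\thost\tframe_offset\n")
        for r in truth:
            fh.write(
                f"{r.name}\t{r.kind}\t{r.start}\t{r.end}\t{r.strand}\t{r.frame_label}\t"
                f"{r.aa_sequence}\t{r.expected_category}\t{r.host or ''}\t"
                f"{'' if r.frame_offset is None else r.frame_offset}\n"
            )


def write_genome_fasta(genome: CircularGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id} topology={genome.topology}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i : i + 70] + "\n")
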
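"""Classification of ORFs against reference annotations.

Mitochondrial genes abut head-to-tail with near-zero spacers, so an ORF can
legitimately overlap two features; the host is the feature with maximal
nucleotide overlap (ties → ``multi_feature`` with every tied host listed).
For a same-strand ORF inside a protein-coding host the relative frame offset
``(orf_start − host_start) mod 3`` on the shared 5'→3' axis separates the
reference reading frame (offset 0) from the two frameshifted ones; antisense
classification deliberately ignores frame.  ORFs hosted by the D-loop are
reported as ``intergenic`` (the category set is about coding/RNA context),
with the D-loop still recorded as host for traceability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils

from .orf_scanner import OrfRecord, _linear_spans

FEATURE_TYPES = ("protein_coding", "rRNA", "tRNA", "D_loop", "micropeptide")

CATEGORIES = (
    "matches_reference",
    "sense_frameshift",
    "antisense",
    "within_rRNA",
    "within_tRNA",
    "intergenic",
    "multi_feature",
)


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature in 1-based closed reference coordinates.

    ``start <= end`` unless the feature wraps the circular origin, in which
    case ``wraps`` is set and the covered span is start..L plus 1..end.
    """

    name: str
    feature_type: str
    start: int
    end: int
    strand: str
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature_type {self.feature_type!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end and not self.wraps:
            raise ValueError(f"{self.name}: start > end without wrap flag")

    def spans(self, genome_length: int) -> list[tuple[int, int]]:
        if not self.wraps:
            return [(self.start, self.end)]
        return [(self.start, genome_length), (1, self.end)]

    @property
    def five_prime_start(self) -> int:
        """Reference position of the feature's 5'-most base on its strand."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class OverlapClassification:
    category: str
    host_feature: str | None
    frame_offset: int | None
    overlap_nt: int
    all_hosts: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class KnownOrf:
    """A known micropeptide entry from the user-editable sidecar file."""

    name: str
    aa_sequence: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None


def frame_offset(orf_start: int, host_start: int, same_strand: bool = True) -> int:
    """Relative frame offset on the shared strand's 5'→3' axis.

    Positions must be expressed on that axis (for minus-strand pairs the
    caller negates reference coordinates, which reverses the direction of
    increase).  Undefined for opposite strands.
    """
    if not same_strand:
        raise ValueError("frame offset is undefined across strands; use the antisense category")
    return (orf_start - host_start) % 3


def _overlap_nt(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    return sum(
        max(0, min(ah, bh) - max(al, bl) + 1) for al, ah in a for bl, bh in b
    )


def classify_orf(
    orf: OrfRecord,
    annotations: list[GeneAnnotation],
    genome_length: int,
) -> OverlapClassification:
    """Classify one ORF against the annotation set (circular-aware)."""
    if not annotations:
        return OverlapClassification("intergenic", None, None, 0)
    orf_spans = _linear_spans(orf, genome_length)
    overlaps = [
        (feat, _overlap_nt(orf_spans, feat.spans(genome_length))) for feat in annotations
    ]
    best = max(o for _, o in overlaps)
    if best == 0:
        return OverlapClassification("intergenic", None, None, 0)
    hosts = [f for f, o in overlaps if o == best]
    if len(hosts) > 1:
        return OverlapClassification(
            "multi_feature", hosts[0].name, None, best, tuple(f.name for f in hosts)
        )
    host = hosts[0]
    if host.feature_type == "rRNA":
        return OverlapClassification("within_rRNA", host.name, None, best)
    if host.feature_type == "tRNA":
        return OverlapClassification("within_tRNA", host.name, None, best)
    if host.feature_type == "D_loop":
        return OverlapClassification("intergenic", host.name, None, best)
    # protein_coding or micropeptide host
    if orf.strand != host.strand:
        return OverlapClassification("antisense", host.name, None, best)
    if orf.strand == "+":
        off = frame_offset(orf.start, host.five_prime_start)
    else:
        # on the minus strand the 5'→3' axis runs with decreasing reference
        # coordinate; negation maps it onto an increasing axis
        off = frame_offset(-orf.start, -host.five_prime_start)
    category = "matches_reference" if off == 0 else "sense_frameshift"
    return OverlapClassification(category, host.name, off, best)


def filter_unannotated(
    orfs: list[OrfRecord],
    annotations: list[GeneAnnotation],
    known_orfs: list[KnownOrf] | None = None,
    genome_length: int | None = None,
) -> list[OrfRecord]:
    """Drop reference-gene records and known micropeptides; keep the rest.

    A record is removed when it classifies as ``matches_reference`` or when
    its peptide equals a known entry's sequence, or its coordinates (and
    strand, when given) coincide with a known entry's.  ORFs inside rRNA and
    tRNA genes are retained — known mitochondrial micropeptides live there.
    """
    known_orfs = known_orfs or []
    if genome_length is None:
        raise ValueError("genome_length is required for circular overlap computation")
    known_seqs = {k.aa_sequence for k in known_orfs if k.aa_sequence}
    known_coords = {
        (k.start, k.end, k.strand)
        for k in known_orfs
        if k.start is not None and k.end is not None
    }
    kept: list[OrfRecord] = []
    for orf in orfs:
        cls = classify_orf(orf, annotations, genome_length)
        if cls.category == "matches_reference":
            continue
        if orf.aa_sequence in known_seqs:
            continue
        if (orf.start, orf.end_no_stop, orf.strand) in known_coords or (
            orf.start,
            orf.end_no_stop,
            None,
        ) in known_coords:
            continue
        kept.append(orf)
    return kept


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_SO_TYPE_MAP = {
    "CDS": "protein_coding",
    "gene": "protein_coding",
    "mRNA": "protein_coding",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "D_loop": "D_loop",
    "D-loop": "D_loop",
    "micropeptide": "micropeptide",
}


def read_annotations_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read features from GFF3, mapping SO terms onto the internal types.

    ``gene`` records are skipped when a CDS with the same Name exists (the
    CDS carries the coding coordinates); unknown feature types are ignored.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feats: list[GeneAnnotation] = []
    cds_names = {
        _feat_name(f) for f in db.all_features() if f.featuretype == "CDS"
    }
    for f in db.all_features():
        ftype = _SO_TYPE_MAP.get(f.featuretype)
        if ftype is None:
            continue
        name = _feat_name(f)
        if f.featuretype == "gene" and name in cds_names:
            continue
        wraps = f.attributes.get("wraps_origin", ["false"])[0] == "true"
        if f.attributes.get("feature_class"):
            ftype = f.attributes["feature_class"][0]
        feats.append(GeneAnnotation(name, ftype, f.start, f.end, f.strand, wraps))
    return feats


def _feat_name(f) -> str:
    for key in ("Name", "ID", "gene"):
        if key in f.attributes:
            return f.attributes[key][0]
    return f"{f.featuretype}_{f.start}"


def write_annotations_gff3(
    annotations: list[GeneAnnotation], path: str | Path, genome_id: str
) -> None:
    so = {"protein_coding": "CDS", "rRNA": "rRNA", "tRNA": "tRNA",
          "D_loop": "D_loop", "micropeptide": "micropeptide"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = f"ID={a.name};Name={a.name}"
            if a.wraps:
                attrs += ";wraps_origin=true"
            fh.write(
                f"{genome_id}\tmtaltorf\t{so[a.feature_type]}\t{a.start}\t{a.end}"
                f"\t.\t{a.strand}\t.\t{attrs}\n"
            )


def read_known_orfs_tsv(path: str | Path) -> list[KnownOrf]:
    """Sidecar TSV: name, aa_sequence, start, end, strand (blank = unknown)."""
    out: list[KnownOrf] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            parts = (line.split("\t") + [""] * 5)[:5]
            name, seq, start, end, strand = (p.strip() for p in parts)
            out.append(
                KnownOrf(
                    name,
                    seq or None,
                    int(start) if start else None,
                    int(end) if end else None,
                    strand or None,
                )
            )
    return out
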
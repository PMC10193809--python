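"""ORF-vs-annotation classification: host assignment by maximal overlap,
relative frame offsets, the unannotated filter, and GFF3 round-tripping."""

import dataclasses

import pytest

from mtaltorf.annotation_overlap import (
    GeneAnnotation,
    KnownOrf,
    classify_orf,
    filter_unannotated,
    frame_offset,
    read_annotations_gff3,
    read_known_orfs_tsv,
    write_annotations_gff3,
)
from mtaltorf.orf_scanner import OrfRecord, frame_of

L = 3000


def orf(start, aa_len, strand="+", mode="stop_to_stop"):
    if strand == "+":
        end = start + 3 * aa_len - 1
    else:
        end = start - 3 * aa_len + 1
    # peptide content is irrelevant to classification; make it start-specific
    # so sequence-based known-ORF matching stays selective
    aa = ("ACDEFGHIKLMNPQRSTVWY" * aa_len)[start % 11 : start % 11 + aa_len]
    return OrfRecord(
        genome_id="g", strand=strand, frame_label=frame_of(start, strand, L),
        start=start, end_no_stop=end, has_stop=True, wraps_origin=False,
        mode=mode, aa_sequence=aa,
    )


@pytest.fixture()
def annotations():
    return [
        GeneAnnotation("geneA", "protein_coding", 101, 703, "+"),   # 200 aa + stop
        GeneAnnotation("geneB", "protein_coding", 901, 1503, "+"),
        GeneAnnotation("rrn", "rRNA", 1601, 2100, "+"),
        GeneAnnotation("trn", "tRNA", 2101, 2170, "+"),
        GeneAnnotation("dloop", "D_loop", 2301, 2900, "+"),
    ]


class TestFrameOffset:
    def test_same_start_is_offset_zero(self):
        assert frame_offset(101, 101) == 0

    @pytest.mark.parametrize("delta,expected", [(797, 2), (4, 1), (3, 0)])
    def test_modular_arithmetic(self, delta, expected):
        assert frame_offset(101 + delta, 101) == expected

    def test_opposite_strand_rejected(self):
        with pytest.raises(ValueError, match="antisense"):
            frame_offset(10, 20, same_strand=False)

    def test_additivity_mod_3(self):
        for a, b, c in [(5, 9, 16), (101, 898, 1557), (1, 2, 3)]:
            assert (frame_offset(a, b) + frame_offset(b, c)) % 3 == frame_offset(a, c)


class TestClassifyOrf:
    def test_reference_frame_orf_matches_reference(self, annotations):
        cls = classify_orf(orf(101, 200), annotations, L)
        assert cls.category == "matches_reference"
        assert cls.host_feature == "geneA" and cls.frame_offset == 0

    def test_sense_frameshift_inside_gene(self, annotations):
        cls = classify_orf(orf(201, 30), annotations, L)
        assert cls.category == "sense_frameshift"
        assert cls.host_feature == "geneA" and cls.frame_offset == (201 - 101) % 3

    def test_antisense_orf_inside_gene(self, annotations):
        cls = classify_orf(orf(400, 30, strand="-"), annotations, L)
        assert cls.category == "antisense" and cls.host_feature == "geneA"
        assert cls.frame_offset is None

    def test_rna_and_trna_hosts(self, annotations):
        assert classify_orf(orf(1700, 30), annotations, L).category == "within_rRNA"
        assert classify_orf(orf(2110, 15), annotations, L).category == "within_tRNA"

    def test_dloop_host_reported_intergenic_with_host(self, annotations):
        cls = classify_orf(orf(2400, 30), annotations, L)
        assert cls.category == "intergenic" and cls.host_feature == "dloop"

    def test_no_overlap_is_intergenic(self, annotations):
        cls = classify_orf(orf(2950, 10), annotations, L)
        assert cls.category == "intergenic" and cls.host_feature is None

    def test_tied_overlap_is_multi_feature_with_all_hosts(self):
        anns = [
            GeneAnnotation("left", "protein_coding", 1, 300, "+"),
            GeneAnnotation("right", "protein_coding", 301, 600, "+"),
        ]
        # 150 nt in each feature
        cls = classify_orf(orf(151, 100), anns, L)
        assert cls.category == "multi_feature"
        assert set(cls.all_hosts) == {"left", "right"}

    def test_minus_strand_gene_frame_offset_axis(self):
        # gene on '-' strand: 5' end at the high coordinate
        anns = [GeneAnnotation("rev", "protein_coding", 101, 700, "-")]
        cls = classify_orf(orf(697, 30, strand="-"), anns, L)
        assert cls.category == "matches_reference" and cls.frame_offset == 0
        cls = classify_orf(orf(695, 30, strand="-"), anns, L)
        assert cls.category == "sense_frameshift" and cls.frame_offset == 2

    def test_rotation_invariance(self, annotations):
        k = 600
        rotated = []
        for a in annotations:
            s = (a.start - 1 + k) % L + 1
            e = (a.end - 1 + k) % L + 1
            rotated.append(dataclasses.replace(a, start=s, end=e, wraps=s > e))
        for o in [orf(201, 30), orf(400, 30, "-"), orf(1700, 30)]:
            ro = dataclasses.replace(
                o, start=(o.start - 1 + k) % L + 1,
                end_no_stop=(o.end_no_stop - 1 + k) % L + 1,
                frame_label=frame_of((o.start - 1 + k) % L + 1, o.strand, L),
            )
            a, b = classify_orf(o, annotations, L), classify_orf(ro, rotated, L)
            assert (a.category, a.host_feature, a.frame_offset) == (
                b.category, b.host_feature, b.frame_offset
            )

    def test_wrapping_feature_overlap(self):
        anns = [GeneAnnotation("wrap", "protein_coding", L - 50, 100, "+", wraps=True)]
        cls = classify_orf(orf(10, 20), anns, L)
        assert cls.host_feature == "wrap" and cls.overlap_nt == 60


class TestFilterUnannotated:
    def test_reference_gene_records_removed(self, annotations):
        gene_orfs = [orf(101, 200), orf(901, 200)]
        assert filter_unannotated(gene_orfs, annotations, [], L) == []

    def test_partition_no_loss(self, annotations):
        orfs = [orf(101, 200), orf(202, 30), orf(400, 25, "-"), orf(2950, 10)]
        kept = filter_unannotated(orfs, annotations, [], L)
        removed = [o for o in orfs if o not in kept]
        assert len(kept) + len(removed) == len(orfs)
        assert all(
            classify_orf(o, annotations, L).category == "matches_reference"
            for o in removed
        )

    def test_known_micropeptides_removed_by_sequence_or_coordinates(self, annotations):
        inside_rrna = orf(1700, 30)
        other = orf(202, 30)
        known_seq = [KnownOrf("HN-like", aa_sequence=inside_rrna.aa_sequence)]
        assert filter_unannotated([inside_rrna, other], annotations, known_seq, L) == [other]
        known_coord = [KnownOrf("HN-like", start=1700, end=1700 + 89)]
        assert filter_unannotated([inside_rrna, other], annotations, known_coord, L) == [other]

    def test_rna_resident_orfs_are_retained_without_known_list(self, annotations):
        inside_rrna = orf(1700, 30)
        assert filter_unannotated([inside_rrna], annotations, [], L) == [inside_rrna]


class TestIO:
    def test_gff3_round_trip(self, tmp_path, annotations):
        p = tmp_path / "ann.gff3"
        write_annotations_gff3(annotations, p, "g")
        back = read_annotations_gff3(p)
        assert {(a.name, a.feature_type, a.start, a.end, a.strand) for a in back} == {
            (a.name, a.feature_type, a.start, a.end, a.strand) for a in annotations
        }

    def test_known_orfs_sidecar_parsing(self, tmp_path):
        p = tmp_path / "known.tsv"
        p.write_text(
            "# comment\nname\taa_sequence\tstart\tend\tstrand\n"
            "Humanin\tMAPRGF\t1634\t1711\t+\nMOTS-c\n"
        )
        known = read_known_orfs_tsv(p)
        assert known[0] == KnownOrf("Humanin", "MAPRGF", 1634, 1711, "+")
        assert known[1] == KnownOrf("MOTS-c", None, None, None, None)

    def test_packaged_sidecar_lists_the_named_micropeptides(self):
        from importlib.resources import files

        path = files("mtaltorf").joinpath("data/known_micropeptides.tsv")
        names = {k.name for k in read_known_orfs_tsv(str(path))}
        assert {"Humanin", "MOTS-c", "gau", "SHMOOSE"} <= names
        assert {f"SHLP{i}" for i in range(1, 7)} <= names
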
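"""Dialect parsing, evidence-vocabulary normalization, identifier mapping."""

import pytest

from mirgold import records
from mirgold.records import (InteractionRecord, map_identifiers,
                             normalize_method, read_id_mapping,
                             read_interactions, write_interactions)


class TestReadInteractions:
    def test_mitab_two_rows_parse_cleanly(self, mitab_file):
        res = read_interactions(mitab_file, "mitab")
        assert len(res.records) == 2 and not res.rejected
        first = res.records[0]
        assert first.mirna_id == "hsa-miR-155-5p"
        assert first.target_id == "PTEN"
        assert first.methods == {"luciferase_reporter"}
        assert first.throughput == "low"  # IMEx-style records are curated
        assert first.pubmed_id == "12345678"
        assert res.records[1].methods == {"rna_ip"}

    def test_mirtarbase_support_field_tokenized_to_vocabulary(self, mirtarbase_file):
        res = read_interactions(mirtarbase_file, "mirtarbase")
        rec = next(r for r in res.records if r.target_id == "PTEN")
        assert rec.methods == {"luciferase_reporter", "western_blot", "qpcr"}

    def test_row_with_empty_mirna_is_rejected_not_dropped(self, mirtarbase_file):
        res = read_interactions(mirtarbase_file, "mirtarbase")
        assert len(res.records) == 4
        assert len(res.rejected) == 1
        assert res.rejected[0].reason == "empty mirna_id"

    def test_weak_support_type_maps_to_high_throughput(self, mirtarbase_file):
        res = read_interactions(mirtarbase_file, "mirtarbase")
        weak = next(r for r in res.records if r.target_id == "MYC")
        assert weak.throughput == "high"

    def test_non_human_rows_rejected_at_parse_time(self, tmp_path):
        p = tmp_path / "mouse.tsv"
        p.write_text(
            "mirna\ttarget\ttaxon\tevidence_code\treference\n"
            "mmu-miR-1\tTrp53\t10090\tluciferase_reporter\tPMID:1\n"
            "hsa-miR-1\tTP53\t9606\tluciferase_reporter\tPMID:2\n")
        res = read_interactions(p, "annotation_export")
        assert [r.target_id for r in res.records] == ["TP53"]
        assert res.rejected[0].reason == "non-human"

    def test_species_conflict_between_interactors_rejected(self, tmp_path):
        p = tmp_path / "conflict.tsv"
        p.write_text(
            "id1\tid2\tcategory1\tcategory2\tspecies1\tspecies2\tmethod\t"
            "score\tpmid\tthroughput\n"
            "hsa-miR-1\tTP53\tmiRNA\tmRNA\tHomo sapiens\tMus musculus\t"
            "Luciferase reporter assay\t0.9\t1\tlow\n")
        res = read_interactions(p, "rnainter")
        assert not res.records
        assert res.rejected[0].reason == "species_conflict"

    def test_record_count_conserved_across_dialects(self, mirtarbase_file, mitab_file):
        for path, dialect, n_rows in [(mirtarbase_file, "mirtarbase", 5),
                                      (mitab_file, "mitab", 2)]:
            res = read_interactions(path, dialect)
            assert len(res.records) + len(res.rejected) == n_rows

    def test_missing_column_and_unknown_dialect_raise(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("mirna\ttarget\nx\ty\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_interactions(bad, "annotation_export")
        with pytest.raises(ValueError, match="unknown dialect"):
            read_interactions(bad, "gaf")
        with pytest.raises(FileNotFoundError):
            read_interactions(tmp_path / "absent.tsv", "mitab")

    @pytest.mark.parametrize("dialect", ["mitab", "mirtarbase", "rnainter",
                                         "annotation_export"])
    def test_write_then_reparse_round_trips(self, tmp_path, dialect, record_factory):
        recs = [
            record_factory(mirna=f"hsa-miR-SIM-{i}", target=f"GENE{i:05d}",
                           methods=m, throughput=tp, source_db=dialect, pmid=str(i))
            for i, (m, tp) in enumerate([
                (("luciferase_reporter",), "low"),
                (("rna_ip", "western_blot"), "low"),
                (("qpcr",), "high" if dialect in ("mirtarbase", "rnainter") else "low"),
            ], start=1)
        ]
        p = tmp_path / "out.tsv"
        write_interactions(recs, p, dialect)
        res = read_interactions(p, dialect)
        assert not res.rejected
        if dialect in ("mitab", "annotation_export"):
            # these dialects carry a single detection method / evidence code
            assert [sorted(r.methods)[0] for r in res.records] == \
                [sorted(r.methods)[0] for r in recs]
        else:
            assert [r.methods for r in res.records] == [r.methods for r in recs]
            assert [r.throughput for r in res.records] == [r.throughput for r in recs]
        # second round trip is exact
        p2 = tmp_path / "out2.tsv"
        write_interactions(res.records, p2, dialect)
        assert read_interactions(p2, dialect).records == res.records


@pytest.mark.parametrize("label,expected", [
    ("Luciferase reporter assay", "luciferase_reporter"),
    ("qRT-PCR", "qpcr"),
    ("Real-time PCR", "qpcr"),
    ("Western blot", "western_blot"),
    ("RNA immunoprecipitation", "rna_ip"),
    ("HITS-CLIP", "clip_seq"),
    ("CLASH", "clash"),
    ("Microarray", "microarray"),
    ("Northern blot", "other"),
    ("rna_ip", "rna_ip"),  # vocabulary tokens are fixed points
])
def test_method_normalization(label, expected):
    assert normalize_method(label) == expected


class TestMapIdentifiers:
    def test_alias_replaced_by_canonical(self, record_factory):
        recs = [record_factory(target="P60484")]
        out, rep = map_identifiers(recs, {"P60484": "PTEN"})
        assert out[0].target_id == "PTEN"
        assert rep.mapped == 1

    def test_empty_mapping_keep_unmapped_is_identity(self, record_factory):
        recs = [record_factory(target=t) for t in ("A", "B")]
        out, rep = map_identifiers(recs, {}, "keep_unmapped")
        assert out == recs
        assert rep.unmapped_kept == 2

    def test_drop_unmapped_counts(self, record_factory):
        recs = [record_factory(target=t) for t in ("A", "B", "X")]
        out, rep = map_identifiers(recs, {"A": "X"}, "drop_unmapped")
        assert [r.target_id for r in out] == ["X", "X"]
        assert (rep.mapped, rep.unmapped_dropped, rep.unchanged) == (1, 1, 1)

    def test_idempotent(self, record_factory):
        recs = [record_factory(target=t) for t in ("P60484", "PTEN", "Q9Y6K9")]
        mapping = {"P60484": "PTEN", "Q9Y6K9": "IKBKG"}
        once, _ = map_identifiers(recs, mapping)
        twice, rep2 = map_identifiers(once, mapping)
        assert twice == once
        assert rep2.mapped == 0

    def test_conflicting_alias_is_hard_error(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("alias\tcanonical\nA\tX\nA\tY\n")
        with pytest.raises(ValueError, match="conflicting mapping"):
            read_id_mapping(p)

    def test_mapping_file_round_trip(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("alias\tcanonical\nP60484\tPTEN\nQ9Y6K9\tIKBKG\n")
        assert read_id_mapping(p) == {"P60484": "PTEN", "Q9Y6K9": "IKBKG"}


def test_record_invariants_enforced():
    with pytest.raises(ValueError):
        InteractionRecord(source_db="excel", mirna_id="m", target_id="g",
                          taxon=9606, methods=frozenset({"other"}),
                          throughput="low")
    with pytest.raises(ValueError):
        InteractionRecord(source_db="mitab", mirna_id="m", target_id="g",
                          taxon=9606, methods=frozenset({"other"}),
                          throughput="medium")
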
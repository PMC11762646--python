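import textwrap

import pytest

from mirgold.records import InteractionRecord


MITAB_TWO_ROWS = (
    "mirbase:hsa-miR-155-5p\tensembl:PTEN\t-\t-\t-\t-\t"
    'psi-mi:"MI:2285"(miRNA luciferase assay)\t-\tpubmed:12345678\t'
    "taxid:9606(Homo sapiens)\ttaxid:9606(Homo sapiens)\t"
    'psi-mi:"MI:0915"(physical association)\tpsi-mi:"MI:0469"(IntAct)\t-\t-\n'
    "mirbase:hsa-miR-21-5p\tensembl:BCL2\t-\t-\t-\t-\t"
    'psi-mi:"MI:1017"(rna immunoprecipitation)\t-\tpubmed:23456789\t'
    "taxid:9606(Homo sapiens)\ttaxid:9606(Homo sapiens)\t"
    'psi-mi:"MI:0915"(physical association)\tpsi-mi:"MI:0469"(IntAct)\t-\t-\n'
)

MIRTARBASE_HEADER = ("mirna\tspecies_mirna\ttarget_gene\tspecies_target\t"
                     "experiments\tsupport_type\tpmid\n")


@pytest.fixture
def mitab_file(tmp_path):
    p = tmp_path / "two.mitab.txt"
    p.write_text(MITAB_TWO_ROWS)
    return p


@pytest.fixture
def mirtarbase_file(tmp_path):
    rows = [
        ("hsa-miR-155-5p", "Homo sapiens", "PTEN", "Homo sapiens",
         "Luciferase reporter assay//Western blot//qRT-PCR",
         "Functional MTI", "11111111"),
        ("hsa-miR-21-5p", "Homo sapiens", "PDCD4", "Homo sapiens",
         "Western blot", "Functional MTI", "22222222"),
        ("", "Homo sapiens", "BCL2", "Homo sapiens",
         "Luciferase reporter assay", "Functional MTI", "33333333"),
        ("hsa-miR-34a-5p", "Homo sapiens", "MYC", "Homo sapiens",
         "qRT-PCR", "Functional MTI (Weak)", "44444444"),
        ("hsa-miR-1-3p", "Homo sapiens", "HDAC4", "Homo sapiens",
         "Luciferase reporter assay", "Functional MTI", "55555555"),
    ]
    p = tmp_path / "mirtarbase.tsv"
    p.write_text(MIRTARBASE_HEADER +
                 "\n".join("\t".join(r) for r in rows) + "\n")
    return p


def make_record(mirna="hsa-miR-1-3p", target="GENE1", methods=("luciferase_reporter",),
                throughput="low", source_db="mirtarbase", pmid="1") -> InteractionRecord:
    return InteractionRecord(source_db=source_db, mirna_id=mirna,
                             target_id=target, taxon=9606,
                             methods=frozenset(methods),
                             throughput=throughput, pubmed_id=pmid)


@pytest.fixture
def record_factory():
    return make_record
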
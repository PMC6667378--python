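import pytest
from hypothesis import settings

from proteopath import (
    KnowledgeBase,
    Participant,
    Pathway,
    Proteoform,
    Ptm,
    Reaction,
    save_kb,
)

settings.register_profile("suite", derandomize=True, max_examples=75)
settings.load_profile("suite")


def _p(acc, isoform=None, *ptms):
    return Proteoform(acc, isoform, tuple(Ptm(t, s) for t, s in ptms))


# hand-authored miniature knowledge base: 12 proteoforms, 6 reactions,
# 4 pathways (PW2 and PW4 are children of PW1)
P10001 = _p("P10001")
P10001_P15 = _p("P10001", None, ("00046", 15))
P10001_P15_T30 = _p("P10001", None, ("00046", 15), ("00047", 30))
P10002 = _p("P10002")
P10002_Y100 = _p("P10002", None, ("00048", 100))
P10003 = _p("P10003")
P10004 = _p("P10004")
P10004_INS = _p("P10004", None, ("00087", 53), ("00798", 31), ("00798", 43))
P10005 = _p("P10005")
P10005_ISO2 = _p("P10005", 2)
P10006 = _p("P10006")
P10006_UNK = Proteoform("P10006", None, (Ptm("00046", None),))

FIXTURE_PROTEOFORMS = (
    P10001, P10001_P15, P10001_P15_T30, P10002, P10002_Y100, P10003,
    P10004, P10004_INS, P10005, P10005_ISO2, P10006, P10006_UNK,
)

FIXTURE_SEQUENCES = {
    "P10001": "MAAAAAAAAPEPTIDERRRRR",   # PEPTIDE at 1-based start 10
    "P10002": "MPEPTIDEKKKKKKKKKKKK",    # PEPTIDE at 1-based start 2
    "P10003": "MGGGGGGGGWWWWGGGGGGG",
    "P10004": "MCCCCCCCCCCCCCCCCCCC",
    "P10005": "MDDDDDDDDDDDDDDDDDDD",
    "P10006": "MEEEEEEEEEEEEEEEEEEE",
}


def make_fixture_kb() -> KnowledgeBase:
    reactions = {
        "R1": Reaction("R1", "Kinase activation", (
            Participant(P10001_P15, "catalyst"),
            Participant(P10001, "input"),
            Participant(P10002_Y100, "output", "complex:C1"),
        )),
        "R2": Reaction("R2", "Substrate conversion", (
            Participant(P10002, "input"),
            Participant(P10003, "output"),
        )),
        "R3": Reaction("R3", "Regulated cleavage", (
            Participant(P10004_INS, "input"),
            Participant(P10001_P15_T30, "regulator"),
        )),
        "R4": Reaction("R4", "Isoform interconversion", (
            Participant(P10005_ISO2, "input"),
            Participant(P10005, "output"),
        )),
        "R5": Reaction("R5", "Stress signal", (
            Participant(P10006_UNK, "input"),
            Participant(P10003, "catalyst", "set:S1"),
        )),
        "R6": Reaction("R6", "Complex assembly", (
            Participant(P10001, "input"),
            Participant(P10002, "input"),
            Participant(P10004, "output"),
            Participant(P10005, "catalyst"),
        )),
    }
    pathways = {
        "PW1": Pathway("PW1", "Signal transduction", None, ("R6",)),
        "PW2": Pathway("PW2", "Receptor cascade", "PW1", ("R1", "R3")),
        "PW3": Pathway("PW3", "Metabolism", None, ("R2", "R4")),
        "PW4": Pathway("PW4", "Stress response", "PW1", ("R5",)),
    }
    gene_map = {
        "GNA1": ("P10001",),
        "GNB2": ("P10002",),
        "GALT": ("P10002",),          # two genes -> one accession (with GNB2)
        "GMULTI": ("P10003", "P10004"),  # one gene -> two accessions
        "GNC5": ("P10005",),
        "GND6": ("P10006",),
    }
    variant_map = {
        "rs100": ("P10001",),
        "rs200": ("P10002", "P10003"),
        "1:12345": ("P10004",),
    }
    return KnowledgeBase(
        proteoforms=FIXTURE_PROTEOFORMS,
        reactions=reactions,
        pathways=pathways,
        gene_map=gene_map,
        variant_map=variant_map,
        sequences=dict(FIXTURE_SEQUENCES),
    )


@pytest.fixture()
def fixture_kb() -> KnowledgeBase:
    return make_fixture_kb()


@pytest.fixture()
def fixture_kb_dir(tmp_path, fixture_kb):
    d = tmp_path / "kb"
    save_kb(fixture_kb, d)
    return d
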
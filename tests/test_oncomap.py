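import pandas as pd
import pytest

from moanet.oncomap import (assign_direction, assign_process,
                            load_canonical_dictionary, map_pathways,
                            match_canonical)

# transcription of published mappings of enriched pathway terms onto the
# canonical oncogenic pathways; the shipped dictionary must reproduce each
TERM_EXPECTATIONS = [
    ("NRF2 pathway", {"NRF2"}),
    ("Nuclear receptor meta-pathway", {"NRF2"}),
    ("TGF-beta Signaling Pathway", {"TGF-beta"}),
    ("Canonical and Non-Canonical TGF-B signaling", {"TGF-beta"}),
    ("Intrinsic Pathway for Apoptosis", {"cell cycle"}),
    ("PTK6 Regulates Cell Cycle", {"cell cycle", "RTK-RAS-MAPK"}),
    ("regulation of intrinsic apoptotic signaling pathway", {"cell cycle"}),
    ("p53 signaling pathway", {"p53"}),
    ("TP53 Regulates Transcription of Cell Cycle Genes", {"p53", "cell cycle"}),
    ("PI3K-Akt-mTOR", {"PI3K/Akt"}),
    ("PI3K-AKT-mTOR signaling pathway and therapeutic opportunities",
     {"PI3K/Akt"}),
    ("PI3K-Akt Signaling Pathway", {"PI3K/Akt"}),
    ("EGF/EGFR Signaling Pathway", {"RTK-RAS-MAPK"}),
    ("Signaling by EGFR", {"RTK-RAS-MAPK"}),
    ("ErbB Signaling Pathway", {"RTK-RAS-MAPK"}),
    ("MAPK Signaling Pathway", {"RTK-RAS-MAPK"}),
    ("VEGFA-VEGFR2 Signaling Pathway", {"RTK-RAS-MAPK"}),
    ("PDGF Pathway", {"RTK-RAS-MAPK"}),
    ("Wnt Signaling Pathway and Pluripotency", {"Wnt/beta-catenin"}),
    ("TCF dependent signaling in response to WNT", {"Wnt/beta-catenin"}),
    ("Notch Signaling Pathway", {"Notch"}),
    ("Signaling by NOTCH1 in Cancer", {"Notch"}),
    ("Apoptosis-related network due to altered Notch3 in ovarian cancer",
     {"Notch", "cell cycle"}),
    ("Pathways Regulating Hippo Signaling", {"Hippo"}),
    ("Cell Cycle, Mitotic", {"cell cycle"}),
    ("Interferon Signaling", {"immune"}),
    ("Interferon gamma signaling", {"immune"}),
    ("TNF signaling pathway", {"immune"}),
    ("TNF alpha Signaling Pathway", {"immune"}),
    ("IL-4 Signaling Pathway", {"immune"}),
    ("IL17 signaling pathway", {"immune"}),
    ("Cytokine Signaling in Immune system", {"immune"}),
    ("Chemokine signaling pathway", {"immune"}),
    ("T cell receptor signaling pathway", {"immune"}),
    ("T-Cell Receptor and Co-stimulatory Signaling", {"immune"}),
    ("B cell receptor signaling pathway", {"immune"}),
    ("Fc epsilon RI signaling pathway", {"immune"}),
    ("Activated TLR4 signalling", {"immune"}),
    ("RIG-I-like Receptor Signaling", {"immune"}),
    ("Negative regulators of RIG-I/MDA5 signaling", {"immune"}),
    ("Inflammatory Response Pathway", {"immune"}),
    ("NF-kB activation through FADD/RIP-1 pathway mediated by caspase-8 and -10",
     {"immune", "cell cycle"}),
]


@pytest.fixture(scope="module")
def dictionary():
    return load_canonical_dictionary()


class TestMatchCanonical:
    @pytest.mark.parametrize("term,expected", TERM_EXPECTATIONS,
                             ids=[t for t, _ in TERM_EXPECTATIONS])
    def test_published_term_assignments(self, dictionary, term, expected):
        assert set(match_canonical(term, dictionary)) >= expected

    @pytest.mark.parametrize("term", [
        "Metabolism of RNA",
        "Metabolism of lipids",
        "rRNA processing",
    ])
    def test_unrelated_terms_do_not_match(self, dictionary, term):
        assert match_canonical(term, dictionary) == []

    def test_vegfr_does_not_leak_into_egfr(self, dictionary):
        # "VEGFR2" contains the letters "EGFR"; the boundary pattern must
        # not fire, only the VEGF pattern should
        hits = match_canonical("VEGFA-VEGFR2 Signaling Pathway", dictionary)
        assert hits == ["RTK-RAS-MAPK"]

    def test_namespaced_terms_match_on_display_name(self, dictionary):
        assert match_canonical("wikipathways::NRF2 pathway", dictionary) == \
            match_canonical("NRF2 pathway", dictionary)


def rows_with(terms, fdr=0.01):
    return pd.DataFrame({"term": list(terms), "fdr": [fdr] * len(terms)})


class TestAssignDirection:
    def test_up_only(self):
        assert assign_direction("T", rows_with(["T"]), rows_with(["X"])) == "up"

    def test_down_only(self):
        assert assign_direction("T", None, rows_with(["T"])) == "down"

    def test_both(self):
        assert assign_direction("T", rows_with(["T"]), rows_with(["T"])) == "both"

    def test_unresolved_when_absent_or_not_significant(self):
        assert assign_direction("T", rows_with(["X"]), rows_with(["Y"])) == \
            "unresolved"
        assert assign_direction("T", rows_with(["T"], fdr=0.2), None) == \
            "unresolved"


class TestAssignProcess:
    def test_apoptosis_term_is_proliferation_category(self, dictionary):
        pa = assign_process("Intrinsic Pathway for Apoptosis",
                            ["cell cycle"], dictionary)
        assert pa.categories == ("cell cycle/proliferation/apoptosis",)

    def test_vegf_term_is_angiogenesis(self, dictionary):
        term = "VEGFA-VEGFR2 Signaling Pathway"
        pa = assign_process(term, match_canonical(term, dictionary), dictionary)
        assert pa.categories == ("angiogenesis",)

    def test_tgf_beta_reports_both_categories(self, dictionary):
        term = "TGF-beta Signaling Pathway"
        pa = assign_process(term, match_canonical(term, dictionary), dictionary,
                            overlap_genes={"SMAD4", "SMAD2"}, direction="down")
        assert set(pa.categories) == {"cell cycle/proliferation/apoptosis",
                                      "metastasis/invasion"}
        assert pa.supporting_genes == ("SMAD2", "SMAD4")

    def test_empty_match_rejected(self, dictionary):
        with pytest.raises(ValueError):
            assign_process("Metabolism of RNA", [], dictionary)


class TestMapPathways:
    def test_every_term_reported_exactly_once(self, dictionary):
        reps = pd.DataFrame({
            "term": ["db::NRF2 pathway", "db::Metabolism of RNA"],
            "fdr": [0.001, 0.002],
            "k": [5, 4],
            "overlap_genes": [frozenset({"NFE2L2", "KEAP1", "GCLC"}),
                              frozenset({"RPL3"})],
        })
        up = rows_with(["db::NRF2 pathway"])
        table = map_pathways(reps, up, None, dictionary=dictionary)
        assert len(table) == 2
        nrf2 = table.set_index("term").loc["db::NRF2 pathway"]
        assert nrf2["matched"]
        assert nrf2["canonical"] == "NRF2"
        assert nrf2["direction"] == "up"
        assert nrf2["category"] == "cell cycle/proliferation/apoptosis"
        unmatched = table.set_index("term").loc["db::Metabolism of RNA"]
        assert not unmatched["matched"]
        assert unmatched["category"] == "unmatched"

    def test_direction_consistent_with_significance(self, dictionary):
        reps = pd.DataFrame({
            "term": ["db::p53 signaling pathway"],
            "fdr": [0.001], "k": [4],
            "overlap_genes": [frozenset({"TP53", "MDM2", "CDKN1A"})],
        })
        table = map_pathways(reps, rows_with(["other"], fdr=0.01),
                             rows_with(["db::p53 signaling pathway"]),
                             dictionary=dictionary)
        assert table.iloc[0]["direction"] == "down"
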
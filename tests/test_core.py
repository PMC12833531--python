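"""Slippery-site scanning, +1 slip emulation, and product classification."""
import pytest
from hypothesis import given, settings, strategies as st

from slipscan import (
    SequenceRecord,
    SlipperyMotif,
    SlipperySite,
    build_frameshift_variant,
    export_putative_peptides,
    oracle_scan,
    predict_frameshift_product,
    scan_slippery_sites,
    translate,
    validate_cds,
)
from slipscan.core import classify_tail
from slipscan.errors import IntegrityError, TranslationError


def cds_of(rna, id="x", **kw):
    return validate_cds(SequenceRecord(id, rna), **kw)


class TestScan:
    @pytest.mark.parametrize(
        "rna, expected",
        [
            # hand enumeration of all codon-aligned 4-mers
            ("AUGUUUCUGAUAAGGUAA", [(3, "UUUC")]),
            ("AUGCUUUCAUAA", []),  # UUUC present at nt 4 but 4 % 3 != 0
            ("AUGAAAGGGUAA", [(3, "AAAG")]),
            ("AUGGCGCAUUAA", []),  # clean
            ("UUUUUUUUUUUU", [(0, "UUUU"), (3, "UUUU"), (6, "UUUU")]),  # poly-U run
            ("AUGUUUUUUUAA", [(3, "UUUU"), (6, "UUUU")]),  # overlapping windows
        ],
    )
    def test_hand_enumerated_examples(self, rna, expected):
        sites = scan_slippery_sites(cds_of(rna))
        assert [(s.nt_start, str(s.motif)) for s in sites] == expected

    def test_sites_carry_frame_invariants(self):
        sites = scan_slippery_sites(cds_of("UUUUUUAAAGGGUUUCAAUAA"))
        assert [(s.nt_start, str(s.motif)) for s in sites] == [
            (0, "UUUU"), (6, "AAAG"), (12, "UUUC"),
        ]
        for site in sites:
            assert site.nt_start == 3 * site.codon_index

    def test_ambiguous_window_skipped_nonstrict(self):
        # N could complete a UUUN window; it is skipped, AAAG still found
        sites = scan_slippery_sites(cds_of("AUGUUUNAAAAAGAAUAA"))
        assert [(s.nt_start, str(s.motif)) for s in sites] == [(9, "AAAG")]

    def test_window_must_fit(self):
        # trailing UUU codon has no 4th base: no site
        assert scan_slippery_sites(cds_of("AUGUUU")) == []

    @settings(max_examples=300, derandomize=True)
    @given(
        st.text(alphabet="ACGU", min_size=3, max_size=120).map(
            lambda s: s[: len(s) // 3 * 3]
        )
    )
    def test_matches_brute_force_oracle(self, rna):
        cds = cds_of(rna)
        got = {(s.nt_start, str(s.motif)) for s in scan_slippery_sites(cds)}
        want = {(s.nt_start, str(s.motif)) for s in oracle_scan(rna)}
        assert got == want


class TestVariant:
    def test_deletes_slipped_base(self):
        cds = cds_of("AUGUUUCUGAUAAGGUAA")
        (site,) = scan_slippery_sites(cds)
        variant = build_frameshift_variant(cds, site)
        assert variant.rna == "AUGUUUUGAUAAGGUAA"
        assert len(variant.rna) == len(cds.rna) - 1

    def test_aaag_variant(self):
        cds = cds_of("AUGAAAGGGUAA")
        (site,) = scan_slippery_sites(cds)
        assert build_frameshift_variant(cds, site).rna == "AUGAAAGGUAA"

    def test_prefix_unchanged(self):
        cds = cds_of("AUGUUUCUGAUAAGGUAA")
        (site,) = scan_slippery_sites(cds)
        variant = build_frameshift_variant(cds, site)
        assert variant.rna[: site.nt_start + 3] == cds.rna[: site.nt_start + 3]

    def test_stale_site_rejected(self):
        cds = cds_of("AUGGCGCAUUAA")
        bogus = SlipperySite("x", 1, 3, SlipperyMotif("UUUC"))
        with pytest.raises(IntegrityError):
            build_frameshift_variant(cds, bogus)


class TestTranslate:
    @pytest.mark.parametrize(
        "rna, peptide, stop",
        [
            ("AUGUUUUGA", "MF", True),
            ("AUGUUU", "MF", False),
            ("AUGUUUCU", "MF", False),  # 2-nt remainder dropped
            ("UAA", "", True),
            ("AUGGCCAUUGUAAUGGGCCGC", "MAIVMGR", False),
        ],
    )
    def test_standard_code(self, rna, peptide, stop):
        assert translate(rna) == (peptide, stop)

    def test_ambiguity_raises_with_position(self):
        with pytest.raises(TranslationError) as err:
            translate("AUGNNNUAA")
        assert err.value.position == 3


class TestProduct:
    def test_null_product_toy(self):
        cds = cds_of("AUGUUUCUGAUAAGGUAA")
        (site,) = scan_slippery_sites(cds)
        product = predict_frameshift_product(cds, site)
        assert product.chimeric_peptide == "MF"
        assert product.native_prefix_aa == 2
        assert product.tail_len_aa == 0
        assert product.stop_in_shifted_frame
        assert product.classification == "null_product"

    def test_short_tail_without_stop(self):
        cds = cds_of("AUGAAAGGGUAA")
        (site,) = scan_slippery_sites(cds)
        product = predict_frameshift_product(cds, site)
        assert product.chimeric_peptide == "MKG"
        assert not product.stop_in_shifted_frame
        assert product.tail_len_aa == 1
        assert product.classification == "short_tail"

    def test_long_tail_threshold_boundary(self):
        # slip at nt 3, then 30 shifted codons before any stop
        rna = "AUG" + "UUUC" + "GCU" * 30 + "UAAUA"  # 3+4+90+5 = 102 nt
        cds = cds_of(rna)
        (site,) = scan_slippery_sites(cds)
        long = predict_frameshift_product(cds, site, min_tail_aa=20)
        assert long.classification == "long_tail"
        assert predict_frameshift_product(cds, site, min_tail_aa=long.tail_len_aa + 1).classification == "short_tail"

    def test_classification_monotone_in_threshold(self, fixture_batch_small):
        order = {"null_product": 0, "short_tail": 1, "long_tail": 2}
        for cds, truth in fixture_batch_small:
            for site in truth:
                previous = None
                for threshold in (0, 1, 5, 20, 100, 10_000):
                    cls = predict_frameshift_product(cds, site, threshold).classification
                    if previous is not None:
                        assert order[cls] <= order[previous]
                    previous = cls

    def test_count_conservation(self, fixture_batch_small):
        """One product per site; deletion never creates an upstream site."""
        for cds, _ in fixture_batch_small:
            sites = scan_slippery_sites(cds)
            products = [predict_frameshift_product(cds, s) for s in sites]
            assert len(products) == len(sites)
            for site in sites:
                variant = build_frameshift_variant(cds, site)
                upstream_parent = [s.nt_start for s in oracle_scan(cds.rna) if s.nt_start < site.nt_start]
                upstream_variant = [s.nt_start for s in oracle_scan(variant.rna) if s.nt_start < site.nt_start]
                assert upstream_variant == upstream_parent


class TestClassifyTail:
    def test_null_regardless_of_threshold(self):
        assert classify_tail(0, 0) == "null_product"
        assert classify_tail(0, 1000) == "null_product"

    def test_threshold_edge(self):
        assert classify_tail(19, 20) == "short_tail"
        assert classify_tail(20, 20) == "long_tail"


class TestExportPeptides:
    def test_header_encodes_site(self, tmp_path):
        cds = cds_of("AUGUUUCUGAUAAGGUAA", id="parent")
        (site,) = scan_slippery_sites(cds)
        product = predict_frameshift_product(cds, site)
        out = tmp_path / "peptides.fasta"
        export_putative_peptides([product], out)
        assert out.read_text() == ">parent|site4|UUUC|null_product\nMF\n"

    def test_empty_list_writes_empty_file(self, tmp_path):
        out = tmp_path / "peptides.fasta"
        export_putative_peptides([], out)
        assert out.read_text() == ""

    def test_two_products_in_site_order(self, tmp_path):
        cds = cds_of("AUGUUUCGCAAAGGGUAA", id="p")
        sites = scan_slippery_sites(cds)
        assert len(sites) == 2
        products = [predict_frameshift_product(cds, s) for s in sites]
        out = tmp_path / "peptides.fasta"
        export_putative_peptides(products, out)
        headers = [l for l in out.read_text().splitlines() if l.startswith(">")]
        assert headers == [">p|site4|UUUC|short_tail", ">p|site10|AAAG|short_tail"]
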
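"""Cohort genomics: status rules, LOH, TMB, spectrum, NNLS, enrichment."""

import numpy as np
import pandas as pd
import pytest

from crisprselect.cohort import (
    ExposureVector,
    build_spectrum96,
    call_loh,
    classify_ercc2_status,
    classify_tp53_status,
    compute_tmb,
    domain_enrichment_test,
    fit_signatures_nnls,
    harmonize_tmb,
)
from crisprselect.sbs import CHANNELS96
from crisprselect.synthetic.cohort import make_synthetic_signatures

HD = [(6, 260), (440, 730)]


def mut_row(gene="ERCC2", vclass="missense", protein_pos=100,
            label="likely_pathogenic", **kw):
    row = dict(sample="S1", gene=gene, chrom="chr19", pos=100, ref="C", alt="T",
               variant_class=vclass, protein_pos=protein_pos,
               pathogenicity_label=label, platform="WES")
    row.update(kw)
    return row


class TestErcc2Status:
    def test_missense_in_helicase_domain_is_mut(self):
        df = pd.DataFrame([mut_row(protein_pos=238)])
        assert classify_ercc2_status(df, HD) == "MUT"

    def test_missense_outside_domains_is_wt(self):
        df = pd.DataFrame([mut_row(protein_pos=312)])
        assert classify_ercc2_status(df, HD) == "WT"

    def test_synonymous_in_domain_is_wt(self):
        df = pd.DataFrame([mut_row(vclass="synonymous", protein_pos=238)])
        assert classify_ercc2_status(df, HD) == "WT"

    @pytest.mark.parametrize("vclass", ["stopgain", "frameshift", "nonstop"])
    def test_truncating_classes_qualify(self, vclass):
        df = pd.DataFrame([mut_row(vclass=vclass, protein_pos=639)])
        assert classify_ercc2_status(df, HD) == "MUT"

    def test_missing_protein_pos_warns_and_skips(self):
        df = pd.DataFrame([mut_row(protein_pos=np.nan)])
        with pytest.warns(UserWarning, match="protein position"):
            assert classify_ercc2_status(df, HD) == "WT"

    def test_order_independent(self):
        rows = [mut_row(protein_pos=312), mut_row(protein_pos=238)]
        assert (classify_ercc2_status(pd.DataFrame(rows), HD)
                == classify_ercc2_status(pd.DataFrame(rows[::-1]), HD) == "MUT")

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            classify_ercc2_status(pd.DataFrame([mut_row()]), [(100, 50)])


class TestTp53Status:
    def test_pathogenic_missense_is_mut(self):
        df = pd.DataFrame([mut_row(gene="TP53", label="pathogenic")])
        assert classify_tp53_status(df) == "MUT"

    def test_vus_only_is_wt(self):
        df = pd.DataFrame([mut_row(gene="TP53", label="uncertain_significance")])
        assert classify_tp53_status(df) == "WT"

    def test_deep_deletion_without_rows_is_mut(self):
        assert classify_tp53_status(pd.DataFrame(columns=["gene"]),
                                    deep_deletion=True) == "MUT"


class TestLoh:
    LOCUS = ("chr19", 45_000_000, 45_020_000)

    def seg(self, start, end, minor, major=2):
        return dict(sample="S1", chrom="chr19", start=start, end=end,
                    major_cn=major, minor_cn=minor)

    def test_minor_zero_overlap_is_loh(self):
        segs = pd.DataFrame([self.seg(44_900_000, 45_100_000, 0)])
        assert call_loh(self.LOCUS, segs) == "LOH"

    def test_minor_retained_is_no_loh(self):
        segs = pd.DataFrame([self.seg(44_900_000, 45_100_000, 1)])
        assert call_loh(self.LOCUS, segs) == "no_LOH"

    def test_no_overlap_is_na(self):
        segs = pd.DataFrame([self.seg(1, 1000, 0)])
        assert call_loh(self.LOCUS, segs) == "NA"

    def test_malformed_segment_rejected(self):
        segs = pd.DataFrame([self.seg(45_100_000, 44_900_000, 0)])
        with pytest.raises(ValueError, match="malformed"):
            call_loh(self.LOCUS, segs)


class TestTmb:
    @pytest.mark.parametrize(
        "count,platform,version,expected",
        [
            (76, "WES", "", 2.0),
            (14, "Caris", "", 10.0),
            (10, "Oncopanel", "v3", 10 / 1.315078),
            (9, "Oncopanel", "v1", 9 / 0.753334),
            (10, "MSK", "410", 10 / 1.016478),
            (12, "MSK", "505", 12 / 1.25964),
        ],
    )
    def test_platform_constants(self, count, platform, version, expected):
        assert compute_tmb(count, platform, version).tmb == pytest.approx(
            expected, rel=1e-12
        )

    def test_unknown_platform_rejected(self):
        with pytest.raises(KeyError, match="unknown platform"):
            compute_tmb(10, "Nanopore")

    def test_zscore_standardization_on_log_scale(self):
        # tmb values chosen so log10(tmb+1) = 1, 2, 3
        recs = [compute_tmb(int(round(t * 38)), "WES", sample=f"S{i}")
                for i, t in enumerate((9, 99, 999))]
        out = harmonize_tmb(recs)
        np.testing.assert_allclose([r.z for r in out], [-1, 0, 1], atol=1e-9)

    def test_zero_spread_stratum_gets_nan_z(self):
        recs = [compute_tmb(38, "WES", sample=s) for s in "ab"]
        with pytest.warns(UserWarning, match="zero spread"):
            out = harmonize_tmb(recs)
        assert all(r.z is None for r in out)

    def test_sample_order_invariant(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 400, size=12)
        recs = [compute_tmb(int(c), "WES", sample=f"S{i}")
                for i, c in enumerate(counts)]
        z1 = {r.sample: r.z for r in harmonize_tmb(recs)}
        z2 = {r.sample: r.z for r in harmonize_tmb(recs[::-1])}
        assert z1.keys() == z2.keys()
        for s in z1:
            assert z1[s] == pytest.approx(z2[s], abs=1e-12)


class TestSpectrum:
    REF = "TACAG"  # positions (1-based from ref_start=100): T=100 ... G=104

    def test_pyrimidine_site_counted_directly(self):
        df = pd.DataFrame([dict(chrom="c", pos=102, ref="C", alt="A")])
        spec = build_spectrum96(df, self.REF, 100)
        assert spec["A[C>A]A"] == 1
        assert spec.sum() == 1

    def test_purine_site_reverse_complemented(self):
        # G>T with 5'A/3'T on the genome strand -> revcomp context A[C>A]T
        df = pd.DataFrame([dict(chrom="c", pos=104, ref="G", alt="T")])
        spec = build_spectrum96(df, self.REF + "T", 100)
        assert spec["A[C>A]T"] == 1

    def test_indels_excluded_from_spectrum(self):
        df = pd.DataFrame([
            dict(chrom="c", pos=102, ref="C", alt="A"),
            dict(chrom="c", pos=102, ref="CA", alt="C"),
        ])
        spec = build_spectrum96(df, self.REF, 100)
        assert spec.sum() == 1

    def test_reference_mismatch_skipped_with_warning(self):
        df = pd.DataFrame([dict(chrom="c", pos=102, ref="G", alt="A")])
        with pytest.warns(UserWarning, match="mismatch"):
            spec = build_spectrum96(df, self.REF, 100)
        assert spec.sum() == 0

    def test_channel_order_is_cosmic_convention(self):
        assert CHANNELS96[0] == "A[C>A]A"
        assert CHANNELS96[16] == "A[C>G]A"
        assert CHANNELS96[-1] == "T[T>G]T"
        assert len(set(CHANNELS96)) == 96


class TestNnls:
    def setup_method(self):
        self.S = make_synthetic_signatures(("S1", "S2", "S3"), seed=7)

    def test_exact_mixture_recovered(self):
        spectrum = (0.7 * self.S["S1"] + 0.3 * self.S["S2"]) * 1000
        fit = fit_signatures_nnls(spectrum, self.S)
        assert fit.exposures["S1"] == pytest.approx(700, abs=1e-6)
        assert fit.exposures["S2"] == pytest.approx(300, abs=1e-6)
        assert fit.exposures["S3"] == pytest.approx(0, abs=1e-6)
        assert fit.residual_norm == pytest.approx(0, abs=1e-6)

    def test_single_signature_spectrum(self):
        fit = fit_signatures_nnls(self.S["S2"] * 500, self.S)
        nonzero = fit.exposures[fit.exposures > 1e-8]
        assert list(nonzero.index) == ["S2"]

    def test_zero_spectrum_gives_zero_exposures(self):
        fit = fit_signatures_nnls(pd.Series(0.0, index=self.S.index), self.S)
        assert (fit.exposures == 0).all()

    def test_objective_matches_projected_gradient_oracle(self):
        rng = np.random.default_rng(5)
        S = self.S.to_numpy()
        StS, L = S.T @ S, np.linalg.eigvalsh(S.T @ S).max()
        for _ in range(5):
            c = rng.random(96) * 20
            fit = fit_signatures_nnls(pd.Series(c, index=self.S.index), self.S)
            x = np.zeros(3)
            for _ in range(20000):
                x = np.maximum(0.0, x - (StS @ x - S.T @ c) / L)
            f_oracle = np.linalg.norm(S @ x - c)
            assert fit.residual_norm == pytest.approx(f_oracle, abs=1e-6)

    def test_invalid_signature_matrix_rejected(self):
        bad = self.S * 2  # columns no longer sum to 1
        with pytest.raises(ValueError, match="sum to 1"):
            fit_signatures_nnls(self.S["S1"], bad)


class TestDomainEnrichment:
    def test_observed_equals_expected_gives_p_one(self):
        res = domain_enrichment_test(56, 100, 0.56)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_enrichment_example(self):
        res = domain_enrichment_test(87, 100, 0.56)
        expected = (87 - 56) ** 2 / 56 + (13 - 44) ** 2 / 44
        assert res.statistic == pytest.approx(expected)
        assert res.statistic == pytest.approx(39.0, abs=5e-3)
        assert res.p < 1e-9

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            domain_enrichment_test(10, 100, 1.0)
        with pytest.raises(ValueError):
            domain_enrichment_test(101, 100, 0.5)
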
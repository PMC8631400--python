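"""Verification criteria (a)-(c), expression-histology correlation, and
tissue-marker classification."""

import numpy as np
import pandas as pd
import pytest

from inflamark.errors import ValidationError
from inflamark.verify import (
    CohortSample,
    classify_tissue_marker,
    correlate_expression_to_histology,
    select_verified_candidates,
)


def samples_for(tissue, scores, groups=None, n_chow=10):
    groups = groups or ["chow"] * n_chow + ["HFD"] * (len(scores) - n_chow)
    return [
        CohortSample(
            sample_id=f"a{i:02d}_{tissue}", group=g, tissue=tissue, histology_score=float(s)
        )
        for i, (g, s) in enumerate(zip(groups, scores))
    ]


class TestSelectionCriteria:
    @pytest.fixture
    def fixture(self):
        cols_l = [f"a{i:02d}_liver" for i in range(27)]
        cols_w = [f"a{i:02d}_WAT" for i in range(27)]
        norm = {
            "liver": pd.DataFrame(
                [[100.0] * 27, [100.0] * 27, [100.0] * 27, [0.1] * 27],
                index=["PASS", "NOTSIG", "LOWER", "UNDETECTED"], columns=cols_l,
            ),
            "WAT": pd.DataFrame(
                [[5.0] * 27, [5.0] * 27, [500.0] * 27, [0.1] * 27],
                index=["PASS", "NOTSIG", "LOWER", "UNDETECTED"], columns=cols_w,
            ),
        }
        de = {
            t: pd.DataFrame(
                {"padj": [0.005, 0.02, 0.005, 0.005]},
                index=["PASS", "NOTSIG", "LOWER", "UNDETECTED"],
            )
            for t in ("liver", "WAT")
        }
        samples = samples_for("liver", np.arange(27) + 1.0) + samples_for(
            "WAT", np.arange(27) + 1.0
        )
        return de, norm, samples

    def test_passing_gene_selected(self, fixture):
        de, norm, samples = fixture
        kept = select_verified_candidates(
            de, norm, samples, {"PASS"}, "liver", fdr_cutoff=0.01
        )
        assert kept == {"PASS"}

    def test_fdr_above_cutoff_excluded(self, fixture):
        de, norm, samples = fixture
        assert select_verified_candidates(de, norm, samples, {"NOTSIG"}, "liver") == set()

    def test_higher_in_other_tissue_excluded(self, fixture):
        de, norm, samples = fixture
        assert select_verified_candidates(de, norm, samples, {"LOWER"}, "liver") == set()
        assert select_verified_candidates(de, norm, samples, {"LOWER"}, "WAT") == {"LOWER"}

    def test_undetected_excluded(self, fixture):
        de, norm, samples = fixture
        assert select_verified_candidates(de, norm, samples, {"UNDETECTED"}, "liver") == set()

    def test_missing_tissue_rejected(self, fixture):
        de, norm, samples = fixture
        with pytest.raises(ValidationError, match="missing"):
            select_verified_candidates({"liver": de["liver"]}, {"liver": norm["liver"]},
                                       samples, {"PASS"}, "WAT")


class TestCorrelation:
    def test_monotone_link_is_exact(self):
        scores = np.linspace(1, 30, 27)
        samples = samples_for("liver", scores)
        norm = pd.DataFrame(
            [np.exp(0.1 * scores), 100.0 / scores],
            index=["UP", "DOWN"], columns=[s.sample_id for s in samples],
        )
        corr = correlate_expression_to_histology(norm, samples, "liver")
        assert corr.loc["UP", "rho"] == pytest.approx(1.0)
        assert corr.loc["DOWN", "rho"] == pytest.approx(-1.0)
        assert bool(corr.loc["UP", "passes"]) and bool(corr.loc["DOWN", "passes"])

    def test_null_markers_rarely_pass(self):
        """Independent expression at n = 27 exceeds |rho| = 0.6 in < 10% of
        500 replicates."""
        rng = np.random.default_rng(99)
        scores = rng.lognormal(1, 0.5, 27)
        samples = samples_for("liver", scores)
        norm = pd.DataFrame(
            rng.normal(100, 10, size=(500, 27)),
            index=[f"N{i}" for i in range(500)],
            columns=[s.sample_id for s in samples],
        )
        corr = correlate_expression_to_histology(norm, samples, "liver")
        assert float(corr["passes"].mean()) < 0.10

    def test_exact_cutoff_does_not_pass(self):
        """|rho| must strictly exceed 0.60; the closed band is 'no relation'."""
        # ranks 1..5 vs permutation (2,1,5,3,4): sum d^2 = 8, rho = 0.6 exactly
        samples = samples_for("liver", [1, 2, 3, 4, 5], groups=["chow"] * 2 + ["HFD"] * 3)
        norm = pd.DataFrame(
            [[1.0, 2.0, 3.0, 5.0, 4.0], [2.0, 1.0, 5.0, 3.0, 4.0]],
            index=["A", "B"], columns=[s.sample_id for s in samples],
        )
        corr = correlate_expression_to_histology(norm, samples, "liver")
        assert corr.loc["B", "rho"] == pytest.approx(0.6)
        assert not bool(corr.loc["B", "passes"])

    def test_constant_gene_gets_nan(self):
        samples = samples_for("liver", [1, 2, 3, 4], groups=["chow", "chow", "HFD", "HFD"])
        norm = pd.DataFrame([[7.0, 7.0, 7.0, 7.0]], index=["C"],
                            columns=[s.sample_id for s in samples])
        corr = correlate_expression_to_histology(norm, samples, "liver")
        assert np.isnan(corr.loc["C", "rho"])
        assert not bool(corr.loc["C", "passes"])

    def test_too_few_animals_rejected(self):
        samples = samples_for("liver", [1, 2], groups=["chow", "HFD"])
        norm = pd.DataFrame([[1.0, 2.0]], index=["G"], columns=[s.sample_id for s in samples])
        with pytest.raises(ValidationError, match=">= 3"):
            correlate_expression_to_histology(norm, samples, "liver")


class TestClassification:
    def test_liver_only_is_hepatic(self):
        # e.g. a haptoglobin-like marker: rho 0.85 in liver, in-band in WAT
        assert classify_tissue_marker(True, False) == "hepatic"

    def test_wat_only_is_adipose(self):
        # e.g. an MMP9-like marker: rho -0.76 in WAT, in-band in liver
        assert classify_tissue_marker(False, True) == "adipose"

    def test_both_and_none(self):
        assert classify_tissue_marker(True, True) == "both"
        assert classify_tissue_marker(False, False) == "none"
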
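"""Published fixed-coefficient scorer, cutoff midpoint and zone logic."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import genotoxpca as g
from genotoxpca.errors import DomainError

FOUR = ("Bax", "Btg2", "Ccng1", "Cdkn1a")


class TestPublishedModel:
    def test_constants(self):
        model = g.published_model()
        assert tuple(model.feature_names_in_) == FOUR
        by_gene = dict(zip(model.feature_names_in_, model.components_[0]))
        assert by_gene["Ccng1"] == -0.516
        mu = dict(zip(model.feature_names_in_, model.mu_))
        assert mu["Cdkn1a"] == 0.402
        sigma = dict(zip(model.feature_names_in_, model.sigma_))
        assert sigma["Ccng1"] == 1.166  # 4-significant-figure pattern
        assert g.PUBLISHED_CUTOFF == -0.507

    def test_score_at_mu_is_origin(self):
        model = g.published_model()
        res = g.score_compound(dict(zip(FOUR, model.mu_)), model)
        assert res.pc1 == pytest.approx(0.0, abs=1e-12)
        assert res.pc2 == pytest.approx(0.0, abs=1e-12)

    def test_unit_profile_hand_value(self):
        # frozen from independent evaluation of the printed coefficients:
        # sum_p a1p * (1 - mu_p) / sigma_p = -1.22877
        res = g.score_compound({gene: 1.0 for gene in FOUR})
        assert res.pc1 == pytest.approx(-1.2288, abs=1e-4)

    def test_missing_gene_rejected(self):
        with pytest.raises(DomainError, match="Cdkn1a"):
            g.score_compound({"Bax": 1.0, "Btg2": 1.0, "Ccng1": 1.0})

    def test_equation_matches_matrix_projection(self):
        """The printed per-gene equations equal the matrix route exactly."""
        model = g.published_model()
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(0.4, 1.0, size=4)
            res = g.score_compound(dict(zip(FOUR, x)), model)
            a1 = model.components_[0]
            a2 = model.components_[1]
            z = (x - model.mu_) / model.sigma_
            assert res.pc1 == pytest.approx(float(a1 @ z), abs=1e-12)
            assert res.pc2 == pytest.approx(float(a2 @ z), abs=1e-12)

    def test_monotone_decreasing_in_each_gene(self):
        base = {gene: 0.0 for gene in FOUR}
        y0 = g.score_compound(base).pc1
        for gene in FOUR:
            bumped = dict(base, **{gene: 0.5})
            assert g.score_compound(bumped).pc1 < y0


def _scores(pc1_by_id):
    return pd.DataFrame(
        {"pc1": list(pc1_by_id.values()), "pc2": 0.0},
        index=pd.Index(pc1_by_id.keys(), name="dose_point"),
    )


class TestCutoff:
    def test_simple_midpoint(self):
        scores = _scores({"G": -2.0, "N": 0.0})
        labels = pd.Series(
            {"G": g.ChemClass.GTHC, "N": g.ChemClass.NGTNHC}
        )
        b = g.derive_cutoff(scores, labels)
        assert b.cutoff == pytest.approx(-1.0)
        assert b.gthc_argmax == "G" and b.nongtx_argmin == "N"

    def test_printed_extremes_give_minus_0973(self):
        """Midpoint of the published extreme scores is -0.973, not the
        printed decision value -0.507; both numbers are surfaced."""
        scores = _scores({"DEN24hL": -1.168, "IND24hH": -0.778})
        labels = pd.Series(
            {"DEN24hL": g.ChemClass.GTHC, "IND24hH": g.ChemClass.NGTNHC}
        )
        b = g.derive_cutoff(scores, labels)
        assert b.cutoff == pytest.approx(-0.973)
        assert g.PUBLISHED_CUTOFF == -0.507
        assert b.cutoff != g.PUBLISHED_CUTOFF

    def test_intermediates_excluded(self):
        scores = _scores({"G": -2.0, "N": 0.0, "I": -5.0})
        labels = pd.Series(
            {
                "G": g.ChemClass.GTHC,
                "N": g.ChemClass.NGTNHC,
                "I": g.ChemClass.INTERMEDIATE,
            }
        )
        assert g.derive_cutoff(scores, labels).cutoff == pytest.approx(-1.0)

    def test_empty_class_rejected(self):
        scores = _scores({"N": 0.0})
        labels = pd.Series({"N": g.ChemClass.NGTNHC})
        with pytest.raises(DomainError, match="GTHC"):
            g.derive_cutoff(scores, labels)

    @settings(max_examples=25, deadline=None)
    @given(shift=st.floats(-10, 10, allow_nan=False))
    def test_shift_equivariance(self, shift):
        scores = _scores({"G1": -3.0, "G2": -2.5, "N1": -0.5, "N2": 1.0})
        labels = pd.Series(
            {
                "G1": g.ChemClass.GTHC,
                "G2": g.ChemClass.GTHC,
                "N1": g.ChemClass.NGTHC,
                "N2": g.ChemClass.NGTNHC,
            }
        )
        c0 = g.derive_cutoff(scores, labels).cutoff
        shifted = scores.copy()
        shifted["pc1"] = shifted["pc1"] + shift
        c1 = g.derive_cutoff(shifted, labels).cutoff
        assert c1 == pytest.approx(c0 + shift, abs=1e-9)


class TestZones:
    BOUNDS_29D = g.ZoneBoundaries(gthc_max_pc1=-2.906, nongtx_min_pc1=0.001)

    @pytest.mark.parametrize(
        "pc1,expected",
        [
            (-4.125, g.Zone.GTHC_ZONE),          # strong coordinate induction
            (-0.651, g.Zone.INTERMEDIATE_ZONE),  # partial signature
            (0.454, g.Zone.NON_GENOTOXIC_ZONE),  # flat marker profile
        ],
    )
    def test_reference_threshold_assignments(self, pc1, expected):
        assert g.classify_zone(pc1, self.BOUNDS_29D) is expected

    def test_boundary_points_belong_to_their_class_zone(self):
        assert g.classify_zone(-2.906, self.BOUNDS_29D) is g.Zone.GTHC_ZONE
        assert g.classify_zone(0.001, self.BOUNDS_29D) is g.Zone.NON_GENOTOXIC_ZONE

    def test_partition_is_total(self):
        for pc1 in np.linspace(-6, 3, 101):
            assert g.classify_zone(pc1, self.BOUNDS_29D) in g.Zone

    def test_inverted_boundaries_rejected(self):
        bad = g.ZoneBoundaries(gthc_max_pc1=1.0, nongtx_min_pc1=-1.0)
        with pytest.raises(DomainError, match="inverted"):
            g.classify_zone(0.0, bad)


class TestZoneClassifierEstimator:
    def test_fit_predict_on_synthetic_study(self, ratios_24h):
        labels = g.labels_for_rows(ratios_24h.rows)
        clf = g.GenotoxZoneClassifier(pca="fit").fit(ratios_24h.data, labels)
        assert clf.boundaries_.separated
        zones = pd.Series(clf.predict(ratios_24h.data), index=ratios_24h.data.index)
        gthc_rows = labels[labels == g.ChemClass.GTHC].index
        assert (zones.loc[gthc_rows] == g.Zone.GTHC_ZONE.value).all()

    def test_decision_function_is_pc1(self, ratios_24h):
        labels = g.labels_for_rows(ratios_24h.rows)
        clf = g.GenotoxZoneClassifier(pca="fit").fit(ratios_24h.data, labels)
        pc1 = clf.pca_.score_frame(ratios_24h.data)["pc1"].to_numpy()
        assert np.allclose(clf.decision_function(ratios_24h.data), pc1)

    def test_published_model_mode(self, ratios_24h):
        labels = g.labels_for_rows(ratios_24h.rows)
        clf = g.GenotoxZoneClassifier(pca="published").fit(ratios_24h.data, labels)
        assert tuple(clf.pca_.feature_names_in_) == FOUR
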
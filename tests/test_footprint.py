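"""Footprint metrics, aggregates, occurrence scores, differential binding."""

import numpy as np
import pandas as pd
import pytest

from ovfield.io import FootprintTrack
from ovfield.footprint import (
    aggregate,
    classify_bound,
    delta_metrics,
    differential_binding,
    footprint_expression_correlation,
    metrics,
    occurrence_scores,
)


def _window(centre_val, flank_val, n=168, centre_halfwidth=12):
    v = np.full(n, flank_val, dtype=float)
    c = n // 2
    v[c - centre_halfwidth : c + centre_halfwidth] = centre_val
    return v


class TestMetrics:
    def test_flat_signal_zero_depth(self):
        m = metrics(np.full(200, 3.7))
        assert m.footprint_depth == pytest.approx(0.0)
        assert m.flanking_accessibility == pytest.approx(3.7)

    def test_unit_flank_zero_centre(self):
        m = metrics(_window(0.0, 1.0))
        assert m.flanking_accessibility == pytest.approx(1.0)
        assert m.footprint_depth == pytest.approx(-1.0)

    def test_piecewise_hand_arithmetic(self):
        m = metrics(_window(0.4, 1.2))
        assert m.footprint_depth == pytest.approx(-0.8)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            metrics(np.ones(100))

    def test_delta(self):
        a = metrics(_window(1.0, 1.0))
        b = metrics(_window(0.0, 1.5))
        d = delta_metrics(a, b)
        assert d["d_flanking"] == pytest.approx(0.5)
        assert d["d_depth"] == pytest.approx(-1.5)


def _track_from_values(vals, chrom="chr1", start=0):
    n = len(vals)
    return FootprintTrack(
        pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(start, start + n),
                "end": np.arange(start + 1, start + n + 1),
                "value": vals,
            }
        )
    )


def _occ(centres, strands=None, peak_ids=None):
    n = len(centres)
    return pd.DataFrame(
        {
            "peak_id": peak_ids if peak_ids is not None else range(n),
            "motif_id": ["m"] * n,
            "tf": ["TF"] * n,
            "chrom": ["chr1"] * n,
            "centre": centres,
            "strand": strands or ["+"] * n,
            "llr_score": [5.0] * n,
        }
    )


class TestAggregate:
    def test_single_occurrence_equals_window(self, rng):
        vals = rng.uniform(1, 3, 600)
        track = _track_from_values(vals)
        prof, n = aggregate(track, _occ([300]), halfwidth=100)
        np.testing.assert_allclose(prof, vals[200:400])
        assert n == 1

    def test_mean_of_two(self, rng):
        vals = rng.uniform(1, 3, 600)
        track = _track_from_values(vals)
        prof, _ = aggregate(track, _occ([200, 400]), halfwidth=50)
        np.testing.assert_allclose(prof, (vals[150:250] + vals[350:450]) / 2)

    def test_minus_strand_window_reversed(self, rng):
        vals = rng.uniform(1, 3, 600)
        track = _track_from_values(vals)
        plus, _ = aggregate(track, _occ([300], ["+"]), halfwidth=80)
        minus, _ = aggregate(track, _occ([300], ["-"]), halfwidth=80)
        np.testing.assert_allclose(minus, plus[::-1])

    def test_partition_associativity(self, rng):
        """Aggregate over all occurrences equals the weighted mean of
        aggregates over a partition of the occurrences."""
        vals = rng.uniform(1, 3, 2000)
        track = _track_from_values(vals)
        centres = [200, 500, 900, 1300, 1700]
        full, n_full = aggregate(track, _occ(centres), halfwidth=60)
        a, na = aggregate(track, _occ(centres[:2]), halfwidth=60)
        b, nb = aggregate(track, _occ(centres[2:]), halfwidth=60)
        np.testing.assert_allclose(full, (na * a + nb * b) / (na + nb))


class TestOccurrenceScores:
    def test_zero_depletion_min_llr_scores_zero(self):
        track = _track_from_values(np.full(400, 2.0))
        occ = _occ([150, 250])
        occ.loc[1, "llr_score"] = 9.0  # occurrence 0 has the minimal llr
        out = occurrence_scores({3: track}, occ)
        assert out.loc[0, "score_d3"] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_depletion(self):
        base = np.full(400, 2.0)
        shallow, deep = base.copy(), base.copy()
        shallow[138:162] -= 0.5
        deep[138:162] -= 1.5
        occ = _occ([150])
        s_shallow = occurrence_scores({3: _track_from_values(shallow)}, occ).loc[0, "score_d3"]
        s_deep = occurrence_scores({3: _track_from_values(deep)}, occ).loc[0, "score_d3"]
        assert s_deep > s_shallow

    def test_bound_unbound_separation_on_synthetic(self, bundle_default, result_default):
        """Scores separate planted bound from unbound occurrences (AUC >= 0.9)."""
        from sklearn.metrics import roc_auc_score

        truth = bundle_default.truth
        planted = pd.DataFrame(truth.planted_motifs)
        planted["bound5"] = planted["bound_days"].apply(lambda d: 5 in d)
        sc = result_default.scores.merge(
            planted, on=["peak_id", "motif_id", "offset", "strand"], how="inner"
        )
        auc = roc_auc_score(sc["bound5"], sc["score_d5"])
        assert auc >= 0.9


class TestClassifyBound:
    def test_constructed_bimodal_recovered(self, rng):
        lo = rng.normal(0.0, 0.05, 60)
        hi = rng.normal(1.0, 0.05, 40)
        scores = pd.Series(np.r_[lo, hi])
        bound = classify_bound(scores, seed=0)
        assert (~bound[:60]).all() and bound[60:].all()

    def test_identical_scores_all_unbound(self):
        assert not classify_bound(pd.Series(np.full(25, 0.3))).any()

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            classify_bound(pd.Series(np.arange(10.0)))

    def test_planted_bound_recovery(self, bundle_default, result_default):
        truth = bundle_default.truth
        planted = pd.DataFrame(truth.planted_motifs)
        planted["bound5"] = planted["bound_days"].apply(lambda d: 5 in d)
        sc = result_default.scores.merge(
            planted, on=["peak_id", "motif_id", "offset", "strand"], how="inner"
        )
        pred = classify_bound(sc["score_d5"], seed=0)
        t = sc["bound5"].to_numpy()
        p = pred.to_numpy()
        balanced_acc = 0.5 * (p[t].mean() + (~p[~t]).mean())
        assert balanced_acc >= 0.9


class TestDifferentialBinding:
    def _scores(self, rng, shift=0.0):
        rows = []
        for m in ("m1", "m2", "m3"):
            for i in range(30):
                a = rng.normal(0, 0.1)
                b = a + (shift if m == "m1" else 0) + rng.normal(0, 0.1)
                rows.append((m, m[0] + "TF", i, a, b))
        return pd.DataFrame(rows, columns=["motif_id", "tf", "occ", "score_d3", "score_d5"])

    def test_identical_days_zero_deltas(self, rng):
        sc = self._scores(rng)
        sc["score_d5"] = sc["score_d3"]
        db = differential_binding(sc, 3, 5)
        np.testing.assert_allclose(db["delta"], 0.0)

    def test_antisymmetry(self, rng):
        sc = self._scores(rng, shift=1.0)
        ab = differential_binding(sc, 3, 5)
        ba = differential_binding(sc, 5, 3)
        np.testing.assert_allclose(ab["delta"], -ba["delta"], atol=1e-12)
        np.testing.assert_allclose(ab["z"], -ba["z"], atol=1e-9)

    def test_z_standardized(self, rng):
        db = differential_binding(self._scores(rng, shift=1.0), 3, 5)
        assert db["z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert db["z"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_planted_gain_ranks_top(self, bundle_default, result_default):
        """Motifs of the upregulated TFs carry the largest binding gains
        between days 3 and 5."""
        truth = bundle_default.truth
        db = result_default.diffbind.sort_values("z", ascending=False)
        activating_motifs = {
            m for m, tf in zip(db.index, db["tf"]) if truth.tf_role.get(tf) == "activator"
        }
        top = set(db.index[: len(activating_motifs)])
        assert len(top & activating_motifs) >= len(activating_motifs) - 1


class TestFootprintExpressionCorrelation:
    def _inputs(self, flip=False):
        days = [0, 1, 2, 3, 5]
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0]], index=["TF"], columns=[f"d{d}" for d in days]
        )
        traj = [1.0, 2.0, 3.0, 4.0, 5.0]
        if flip:
            traj = traj[::-1]
        sc = pd.DataFrame(
            {
                "motif_id": ["m"] * 3,
                "tf": ["TF"] * 3,
                **{f"score_d{d}": [traj[i]] * 3 for i, d in enumerate(days)},
            }
        )
        return sc, expr

    def test_equal_trajectories_r_one(self):
        sc, expr = self._inputs()
        out = footprint_expression_correlation(sc, expr)
        assert out.loc["m", "median_r"] == pytest.approx(1.0)

    def test_anticorrelated_ramp(self):
        sc, expr = self._inputs(flip=True)
        out = footprint_expression_correlation(sc, expr)
        assert out.loc["m", "median_r"] == pytest.approx(-1.0)

    def test_activators_high_in_efup_tads(self, bundle_default, result_default):
        truth = bundle_default.truth
        best = result_default.fp_expr_corr_efup.groupby("tf")["median_r"].max()
        for tf, role in truth.tf_role.items():
            if role == "activator":
                assert best[tf] > 0.5
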
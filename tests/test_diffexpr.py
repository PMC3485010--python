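import math

import numpy as np
import pandas as pd
import pytest

from osteomir.diffexpr import (
    annotate_families,
    bh_adjust,
    differential_features,
    fold_change,
    group_t_test,
)
from osteomir.io_formats import (
    ExpressionMatrix,
    MirnaAnnotation,
    SampleAnnotation,
    ValidationError,
)
from osteomir.preprocess import PresenceRule


def _two_groups(a_rows, b_rows):
    """Build a matrix with len(a_rows[0]) group-a and len(b_rows[0]) group-b samples."""
    a = np.asarray(a_rows, dtype=float)
    b = np.asarray(b_rows, dtype=float)
    sample_ids = [f"A{i}" for i in range(a.shape[1])] + [f"B{i}" for i in range(b.shape[1])]
    groups = {s: ("cell_line" if s.startswith("A") else "bone") for s in sample_ids}
    m = ExpressionMatrix(
        [f"f{i}" for i in range(a.shape[0])], sample_ids, np.hstack([a, b])
    )
    return m, SampleAnnotation.from_mapping(groups)


def _welch_oracle(a, b):
    """Textbook Welch formula, independent of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    from scipy import stats

    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestGroupTTest:
    def test_identical_groups_give_t0_p1(self):
        m, ann = _two_groups([[1, 2, 3]], [[1, 2, 3]])
        res = group_t_test(m, ann, "cell_line", "bone")
        assert res["t_stat"].iloc[0] == 0.0
        assert res["p_raw"].iloc[0] == 1.0

    def test_extreme_separation(self):
        m, ann = _two_groups([[0, 1e-9]], [[10, 10 + 1e-9]])
        res = group_t_test(m, ann, "cell_line", "bone")
        assert res["p_raw"].iloc[0] < 1e-6

    def test_matches_hand_welch_formula(self):
        a, b = [1, 2, 3, 4], [3, 4, 5, 6]
        m, ann = _two_groups([a], [b])
        res = group_t_test(m, ann, "cell_line", "bone")
        t, p = _welch_oracle(a, b)
        assert res["t_stat"].iloc[0] == pytest.approx(t, abs=1e-12)
        assert res["p_raw"].iloc[0] == pytest.approx(p, abs=1e-12)

    def test_zero_variance_equal_means_p_one(self):
        m, ann = _two_groups([[2, 2, 2]], [[2, 2]])
        res = group_t_test(m, ann, "cell_line", "bone")
        assert res["p_raw"].iloc[0] == 1.0

    def test_zero_variance_separated_p_zero(self):
        m, ann = _two_groups([[0, 0]], [[10, 10]])
        res = group_t_test(m, ann, "cell_line", "bone")
        assert res["p_raw"].iloc[0] == 0.0

    def test_group_of_one_rejected(self):
        m, ann = _two_groups([[1]], [[1, 2]])
        with pytest.raises(ValidationError):
            group_t_test(m, ann, "cell_line", "bone")


def _bh_oracle(p):
    """Definition-based step-up: sort, q_i = p_i * m / i, enforce monotonicity
    from the largest rank down, cap at 1, restore input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=40)
        assert (bh_adjust(p) >= p - 1e-12).all()

    def test_matches_definition_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 51))
            np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestFoldChange:
    @pytest.mark.parametrize(
        "mean_a,mean_b,expected", [(5, 3, 4.0), (3, 5, -4.0), (4, 4, 1.0)]
    )
    def test_sign_convention(self, mean_a, mean_b, expected):
        m, ann = _two_groups([[mean_a, mean_a]], [[mean_b, mean_b]])
        fc = fold_change(m, ann, "cell_line", "bone")["fold_change"].iloc[0]
        assert fc == pytest.approx(expected)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        m, ann = _two_groups(rng.normal(8, 1, (10, 3)), rng.normal(7, 1, (10, 2)))
        ab = fold_change(m, ann, "cell_line", "bone")["fold_change"].to_numpy()
        ba = fold_change(m, ann, "bone", "cell_line")["fold_change"].to_numpy()
        np.testing.assert_allclose(ab, -ba)
        assert (np.abs(ab) >= 1.0).all()


class TestDifferentialFeatures:
    def test_alpha_zero_gives_no_hits(self, default_cohort):
        c = default_cohort
        recs = differential_features(
            c.mirna, c.detection, c.annotation, PresenceRule(), alpha=0.0
        )
        assert not recs["significant"].any()

    def test_planted_effects_recovered(self, default_cohort):
        c = default_cohort
        recs = differential_features(c.mirna, c.detection, c.annotation, PresenceRule())
        hits = set(recs.loc[recs["significant"], "feature_id"])
        truth = set(c.truth.de_mirna_ids)
        assert len(hits & truth) / len(truth) >= 0.9
        assert len(hits - truth) <= 2

    def test_zero_noise_fold_change_exact(self, noiseless_cohort):
        c = noiseless_cohort
        recs = differential_features(c.mirna, c.detection, c.annotation, PresenceRule())
        recs = recs.set_index("feature_id")
        for mirna, sign in c.truth.de_mirna:
            assert recs.loc[mirna, "fold_change"] == pytest.approx(sign * 4.0, rel=1e-9)

    def test_presence_counts_reported(self, default_cohort):
        c = default_cohort
        recs = differential_features(c.mirna, c.detection, c.annotation, PresenceRule())
        assert (recs["presence_a"] <= 19).all()
        assert (recs["presence_b"] <= 4).all()

    def test_bh_runs_over_filtered_set_only(self, default_cohort):
        c = default_cohort
        filtered = differential_features(c.mirna, c.detection, c.annotation, PresenceRule())
        unfiltered = differential_features(c.mirna, None, c.annotation, None)
        assert len(filtered) < len(unfiltered)
        # same feature, same raw p, different adjustment universe
        f0 = filtered["feature_id"].iloc[0]
        p_f = filtered.set_index("feature_id").loc[f0]
        p_u = unfiltered.set_index("feature_id").loc[f0]
        assert p_f["p_raw"] == pytest.approx(p_u["p_raw"])


class TestAnnotateFamilies:
    def _records(self, ids, significant=None):
        significant = significant if significant is not None else [True] * len(ids)
        return pd.DataFrame({"feature_id": ids, "significant": significant})

    def test_two_families_of_two_plus_singletons(self):
        ids = ["m1", "m2", "m3", "m4", "m5", "m6"]
        ann = [
            MirnaAnnotation("m1", family_id="famA"),
            MirnaAnnotation("m2", family_id="famA"),
            MirnaAnnotation("m3", family_id="famB"),
            MirnaAnnotation("m4", family_id="famB"),
            MirnaAnnotation("m5", family_id="famC"),
            MirnaAnnotation("m6"),
        ]
        _, summary = annotate_families(self._records(ids), ann)
        assert summary["n_shared_family_or_cluster"] == 4
        assert summary["n_in_family"] == 5

    def test_cluster_mates_counted_as_shared(self):
        ids = ["m1", "m2"]
        ann = [
            MirnaAnnotation("m1", cluster_id="miR-17-92"),
            MirnaAnnotation("m2", cluster_id="miR-17-92"),
        ]
        _, summary = annotate_families(self._records(ids), ann)
        assert summary["n_shared_family_or_cluster"] == 2

    def test_no_annotation_gives_zero_counts(self):
        _, summary = annotate_families(self._records(["m1", "m2"]), [])
        assert summary["n_in_family"] == 0
        assert summary["n_shared_family_or_cluster"] == 0
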
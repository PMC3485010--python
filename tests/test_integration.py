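import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from osteomir.integration import (
    PairRecord,
    anticorrelation_filter,
    candidate_pairs,
    conservation_filter,
    correlate_features,
    hypergeometric_overlap,
    multi_mirna_targets,
    pair_correlations,
    run_cascade,
)
from osteomir.io_formats import ExpressionMatrix, TargetPrediction, ValidationError


def _pred(mirna, gene, pct=0.8):
    star = mirna.endswith("*")
    return TargetPrediction(mirna, mirna, gene, f"NM_{gene}", None if star else pct, star)


def _pair(mirna="miR-1", gene="G1", r=None, pct=0.8, star=False):
    return PairRecord(mirna, gene, f"NM_{gene}", pct, star, r=r)


class TestCandidatePairs:
    def test_enumerated_fixture(self):
        preds = [
            _pred("miR-a", "G1"),
            _pred("miR-a", "G2"),
            _pred("miR-b", "G3"),
            _pred("miR-c", "G4"),
        ]
        pairs = candidate_pairs(
            ["miR-a", "miR-b", "miR-c"], preds,
            de_mrnas_cl=["G1", "G2", "G3"], de_mrnas_clin=["G1", "G3", "G4"],
        )
        assert {(p.mirna_id, p.gene_symbol) for p in pairs} == {("miR-a", "G1"), ("miR-b", "G3")}
        for p in pairs:
            assert p.stage_flags == {"predicted", "cohort_confirmed"}

    def test_single_cohort_gene_excluded(self):
        pairs = candidate_pairs(["miR-a"], [_pred("miR-a", "G1")], ["G1"], [])
        assert pairs == []

    def test_no_de_mirnas_empty(self):
        assert candidate_pairs([], [_pred("miR-a", "G1")], ["G1"], ["G1"]) == []

    def test_empty_predictions_warn_and_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert candidate_pairs(["miR-a"], [], ["G1"], ["G1"]) == []
        assert "empty prediction table" in caplog.text


def _expr(feature_values: dict[str, list[float]]) -> ExpressionMatrix:
    ids = list(feature_values)
    values = np.array([feature_values[f] for f in ids], dtype=float)
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(ids, samples, values)


class TestPairCorrelations:
    def test_perfect_anticorrelation(self):
        mir = _expr({"miR-a": [1, 2, 3, 4, 5]})
        mr = _expr({"G1": [5, 4, 3, 2, 1]})
        (pair,) = pair_correlations([_pair("miR-a", "G1")], mir, mr, mir.sample_ids)
        assert pair.r == pytest.approx(-1.0)

    def test_linear_negative_with_offset(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        mir = _expr({"miR-a": x})
        mr = _expr({"G1": (-1.0 * x + 10.0)})
        (pair,) = pair_correlations([_pair("miR-a", "G1")], mir, mr, mir.sample_ids)
        assert pair.r == pytest.approx(-1.0)

    def test_agrees_with_naive_two_pass_oracle(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=19)
        y = rng.normal(size=19)
        mir, mr = _expr({"m": x}), _expr({"g": y})
        (pair,) = pair_correlations([_pair("m", "g")], mir, mr, mir.sample_ids)
        mx, my = x.mean(), y.mean()
        oracle = ((x - mx) * (y - my)).sum() / math.sqrt(
            ((x - mx) ** 2).sum() * ((y - my) ** 2).sum()
        )
        assert pair.r == pytest.approx(oracle, abs=1e-12)

    def test_decoy_pairs_center_near_zero(self):
        rng = np.random.default_rng(7)
        mir = _expr({"m": rng.normal(size=19)})
        rs = []
        for _ in range(100):
            mr = _expr({"g": rng.normal(size=19)})
            (pair,) = pair_correlations([_pair("m", "g")], mir, mr, mir.sample_ids)
            rs.append(pair.r)
        assert abs(np.mean(rs)) < 0.15

    def test_multi_probe_gene_uses_most_anticorrelated(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        mir = _expr({"m": x})
        mr = _expr({"p1": -x, "p2": x})
        (pair,) = pair_correlations(
            [_pair("m", "G")], mir, mr, mir.sample_ids,
            gene_to_probes={"G": ["p1", "p2"]},
        )
        assert pair.r == pytest.approx(-1.0)
        assert pair.probe_id == "p1"
        (strict,) = pair_correlations(
            [_pair("m", "G")], mir, mr, mir.sample_ids,
            gene_to_probes={"G": ["p1", "p2"]}, require_all_probes=True,
        )
        assert strict.r == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        mir = _expr({"m": [1, 2]})
        mr = _expr({"g": [2, 1]})
        with pytest.raises(ValidationError):
            pair_correlations([_pair("m", "g")], mir, mr, mir.sample_ids)


class TestFilters:
    def test_anticorrelation_boundary_is_strict(self):
        pairs = [_pair(r=-0.51), _pair(r=-0.50), _pair(r=0.9)]
        kept = anticorrelation_filter(pairs)
        assert [p.r for p in kept] == [-0.51]
        assert "anticorrelated" in kept[0].stage_flags

    def test_threshold_minus_one_keeps_nothing(self):
        assert anticorrelation_filter([_pair(r=-1.0)], r_threshold=-1.0) == []

    def test_conservation_boundary_keeps_equal(self):
        pairs = [_pair(gene="G1", pct=0.39), _pair(gene="G2", pct=0.40)]
        kept = conservation_filter(pairs)
        assert [p.gene_symbol for p in kept] == ["G2"]

    def test_star_strand_without_pct_retained(self):
        (kept,) = conservation_filter([_pair(mirna="miR-21*", pct=None, star=True)])
        assert kept.pct is None
        assert "conserved" in kept.stage_flags

    def test_all_pct_one_all_kept(self):
        pairs = [_pair(gene=f"G{i}", pct=1.0) for i in range(5)]
        assert len(conservation_filter(pairs)) == 5


class TestMultiMirnaTargets:
    def test_table_shape_fixture(self):
        pairs = [
            _pair("miR-29a", "CPEB3"),
            _pair("miR-29b", "CPEB3"),
            _pair("miR-9", "TGFBR2"),
            _pair("miR-195", "SOX5"),
            _pair("miR-497", "SOX5"),
            _pair("miR-503", "SOX5"),
            _pair("miR-7", "IRS2"),
        ]
        groups = multi_mirna_targets(pairs)
        assert list(groups) == ["CPEB3", "SOX5"]
        assert groups["CPEB3"] == ["miR-29a", "miR-29b"]
        assert groups["SOX5"] == ["miR-195", "miR-497", "miR-503"]

    def test_single_mirna_gene_excluded(self):
        assert multi_mirna_targets([_pair("miR-1", "G")]) == {}

    def test_duplicate_pairs_count_once(self):
        pairs = [_pair("miR-1", "G"), _pair("miR-1", "G")]
        assert multi_mirna_targets(pairs) == {}


def _hypergeom_oracle(N, K, n, k):
    """Exact rational upper tail by enumeration of binomial coefficients."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
    return total


class TestHypergeometricOverlap:
    def test_worked_example(self):
        universe = [f"g{i}" for i in range(10)]
        a, b = universe[:4], universe[:4] + [universe[5]]
        res = hypergeometric_overlap(a, b, universe)
        assert res.n_overlap == 4
        assert res.p == pytest.approx(5 / 210, rel=1e-9)
        assert res.log10_p == pytest.approx(math.log10(5 / 210), abs=1e-6)

    def test_set_equal_to_universe_forced_overlap(self):
        universe = [f"g{i}" for i in range(8)]
        res = hypergeometric_overlap(universe, universe[:3], universe)
        assert res.log10_p == 0.0

    def test_zero_overlap_upper_tail_is_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = hypergeometric_overlap(universe[:3], universe[5:8], universe)
        assert res.log10_p == pytest.approx(0.0, abs=1e-9)

    def test_matches_exact_rational_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            N = int(rng.integers(5, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            a = list(rng.choice(universe, size=K, replace=False))
            b = list(rng.choice(universe, size=n, replace=False))
            k = len(set(a) & set(b))
            res = hypergeometric_overlap(a, b, universe)
            oracle = float(_hypergeom_oracle(N, K, n, k))
            assert 10.0**res.log10_p == pytest.approx(oracle, rel=1e-8)

    def test_not_subset_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_overlap(["x"], ["a"], ["a", "b"])

    def test_log_space_survives_extreme_overlaps(self):
        # overlap so complete that the plain p-value underflows a double
        universe = [f"g{i}" for i in range(40000)]
        a = universe[:9000]
        b = universe[:9000]
        res = hypergeometric_overlap(a, b, universe)
        assert res.log10_p < -1000


class TestCorrelateFeatures:
    def test_identical_and_antiproportional(self):
        a = _expr({"f": [1.0, 2.0, 3.0]})
        b = _expr({"g": [2.0, 4.0, 6.0], "h": [-2.0, -4.0, -6.0]})
        res = correlate_features(a, b, [("f", "g"), ("f", "h")])
        assert res["r"].tolist() == pytest.approx([1.0, -1.0])

    def test_hand_oracle(self):
        a = _expr({"f": [1, 2, 3, 4]})
        b = _expr({"g": [1, 3, 2, 4]})
        res = correlate_features(a, b, [("f", "g")])
        assert res["r"].iloc[0] == pytest.approx(0.8, abs=1e-12)

    def test_host_gene_positively_correlated(self, default_cohort):
        c = default_cohort
        cl = c.truth.groups["cell_line"]
        pairs = [
            (members[0], c.truth.host_genes[cid])
            for cid, members in c.truth.clusters.items()
            if cid in c.truth.host_genes
        ]
        res = correlate_features(c.mirna, c.mrna, pairs, sample_subset=cl)
        assert (res["r"] > 0.6).all()


class TestCascade:
    def test_monotone_and_flags(self, default_cohort):
        from osteomir import diffexpr as de
        from osteomir.preprocess import PresenceRule

        c = default_cohort
        dm = de.differential_features(c.mirna, c.detection, c.annotation, PresenceRule())
        hits = dm.loc[dm["significant"], "feature_id"].tolist()
        cl = de.differential_features(c.mrna, None, c.annotation, None, "cell_line", "bone")
        cli = de.differential_features(c.mrna, None, c.annotation, None, "clinical", "bone")
        res = run_cascade(
            hits, c.predictions,
            cl.loc[cl["significant"], "feature_id"].tolist(),
            cli.loc[cli["significant"], "feature_id"].tolist(),
            c.mirna, c.mrna, c.truth.groups["cell_line"],
        )
        ns = [n_out for _, _, n_out, _ in res.audit]
        for (_, n_in, n_out, _) in res.audit:
            assert n_out <= n_in
        for p in res.pairs:
            assert {"predicted", "cohort_confirmed", "anticorrelated", "conserved"} <= set(p.stage_flags)
        # final pair set is a subset of the candidate set
        cands = candidate_pairs(
            hits, c.predictions,
            cl.loc[cl["significant"], "feature_id"].tolist(),
            cli.loc[cli["significant"], "feature_id"].tolist(),
        )
        cand_keys = {(p.mirna_id, p.gene_symbol) for p in cands}
        assert {(p.mirna_id, p.gene_symbol) for p in res.pairs} <= cand_keys
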
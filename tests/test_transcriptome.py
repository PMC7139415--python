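import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import gsea_es_naive, ssgsea_naive
from gfscan.transcriptome import (
    assign_subtype,
    differential_expression,
    gsea_two_class,
    ntp_classify,
    ssgsea_scores,
    tumor_intrinsic_filter,
)


def expr(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestIntrinsicFilter:
    def paired(self, rng, n_genes=30, n_pairs=12):
        g = rng.normal(5, 1, size=(n_genes, n_pairs))
        gsc = expr(g)
        tissue = expr(g + rng.normal(0, 0.01, size=g.shape),
                      samples=[f"s{j}-T" for j in range(n_pairs)])
        pairs = {f"s{j}": f"s{j}-T" for j in range(n_pairs)}
        return gsc, tissue, pairs

    def test_identical_ranks_kept_reversed_dropped(self, rng):
        gsc, tissue, pairs = self.paired(rng)
        # anti-monotone tissue profile for one gene: rho = -1
        tissue.iloc[0] = 12.0 - gsc.iloc[0].to_numpy()
        kept, report = tumor_intrinsic_filter(gsc, tissue, pairs)
        assert "g0" not in kept and report.loc["g0", "reason"] == "low_correlation"
        assert report.loc["g1", "rho"] > 0.99 and "g1" in kept

    def test_rho_threshold_is_inclusive(self, rng):
        gsc, tissue, pairs = self.paired(rng)
        kept, report = tumor_intrinsic_filter(gsc, tissue, pairs, rho_min=1.0)
        exact = report[np.isclose(report["rho"], 1.0)]
        assert set(exact.index) <= set(kept)

    def test_mostly_zero_and_unannotated_genes_dropped(self, rng):
        gsc, tissue, pairs = self.paired(rng)
        gsc.iloc[2, : 7] = 0.0  # zero in 7/12 stem-cell samples
        kept, report = tumor_intrinsic_filter(
            gsc, tissue, pairs, annotated=[g for g in gsc.index if g != "g3"]
        )
        assert report.loc["g2", "reason"] == "mostly_zero"
        assert report.loc["g3", "reason"] == "unannotated"

    def test_sample_order_invariance(self, rng):
        gsc, tissue, pairs = self.paired(rng)
        kept1, _ = tumor_intrinsic_filter(gsc, tissue, pairs)
        kept2, _ = tumor_intrinsic_filter(
            gsc[gsc.columns[::-1]], tissue[tissue.columns[::-1]], pairs
        )
        assert kept1 == kept2

    def test_too_few_pairs_rejected(self, rng):
        gsc, tissue, pairs = self.paired(rng, n_pairs=4)
        with pytest.raises(ValueError):
            tumor_intrinsic_filter(gsc, tissue, pairs)


class TestDifferentialExpression:
    def test_null_gene_not_deg_shifted_gene_deg(self, rng):
        a = rng.normal(0, 1, size=(2, 20))
        a[1, 10:] += 10  # second gene strongly shifted in group b
        e = expr(a)
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=e.columns)
        out = differential_expression(e, labels)
        assert not out.loc["g0", "is_deg"]
        assert out.loc["g1", "is_deg"] and out.loc["g1", "direction"] == -1

    def test_constant_gene_gets_p_one(self):
        e = expr(np.ones((1, 8)))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=e.columns)
        out = differential_expression(e, labels)
        assert out.loc["g0", "p"] == 1.0

    def test_spike_in_recall_and_false_positive_rate(self, rng):
        recalls, fprs = [], []
        for seed in range(20):
            r = np.random.default_rng(seed)
            null = r.normal(0, 1, size=(100, 20))
            shifted = r.normal(0, 1, size=(10, 20))
            shifted[:, 10:] += 3.0
            e = expr(np.vstack([null, shifted]))
            labels = pd.Series(["a"] * 10 + ["b"] * 10, index=e.columns)
            out = differential_expression(e, labels)
            recalls.append(out["is_deg"].iloc[100:].mean())
            fprs.append((out["p"].iloc[:100] <= 0.05).mean())
        assert np.mean(recalls) >= 0.90
        assert np.mean(fprs) <= 0.05 + 0.05

    def test_group_size_validation(self, rng):
        e = expr(rng.normal(size=(5, 5)))
        labels = pd.Series(["a"] * 2 + ["b"] * 3, index=e.columns)
        with pytest.raises(ValueError):
            differential_expression(e, labels)


class TestNtp:
    def toy(self, rng, n_extra=30, n_markers=12, n_samples=8):
        genes = (
            [f"ma{i}" for i in range(n_markers)]
            + [f"mb{i}" for i in range(n_markers)]
            + [f"x{i}" for i in range(n_extra)]
        )
        e = expr(rng.normal(0, 1, size=(len(genes), n_samples)), genes=genes)
        templates = {
            "A": [f"ma{i}" for i in range(n_markers)],
            "B": [f"mb{i}" for i in range(n_markers)],
        }
        return e, templates

    def test_template_like_sample_gets_distance_zero_and_min_p(self, rng):
        e, templates = self.toy(rng)
        z_target = np.zeros(len(e.index))
        z_target[:12] = 3.0
        z_target[12:24] = -3.0
        e["s0"] = e.mean(axis=1) + z_target * 10  # dominate standardization
        out = ntp_classify(e, templates, n_perm=100, seed=1)
        assert out.loc["s0", "predicted"] == "A"
        assert out.loc["s0", "p"] <= 2 / 101

    def test_class_recovery_on_planted_samples(self, rng):
        e, templates = self.toy(rng)
        for j, s in enumerate(e.columns):
            own = templates["A"] if j % 2 == 0 else templates["B"]
            e.loc[own, s] += 4.0
        out = ntp_classify(e, templates, n_perm=100, seed=0)
        want = ["A" if j % 2 == 0 else "B" for j in range(len(e.columns))]
        assert list(out["predicted"]) == want

    def test_overlapping_templates_rejected(self, rng):
        e, templates = self.toy(rng)
        templates["B"][0] = templates["A"][0]
        with pytest.raises(ValueError, match="disjoint"):
            ntp_classify(e, templates)

    def test_row_order_and_gene_rescaling_invariance(self, rng):
        e, templates = self.toy(rng)
        out1 = ntp_classify(e, templates, n_perm=50, seed=3)
        shuffled = e.sample(frac=1, random_state=0)
        rescaled = shuffled.mul(
            np.abs(np.random.default_rng(1).normal(2, 0.5, len(shuffled))), axis=0
        )
        out2 = ntp_classify(rescaled, templates, n_perm=50, seed=3)
        assert list(out1["predicted"]) == list(out2["predicted"])
        assert out1["distance"].to_numpy() == pytest.approx(out2["distance"].to_numpy())

    def test_exhaustive_permutation_on_tiny_instance(self, rng):
        # 3 non-marker + 4 marker genes: compare p against full enumeration
        genes = ["ma0", "ma1", "mb0", "mb1", "x0", "x1", "x2"]
        e = expr(rng.normal(size=(7, 5)), genes=genes)
        templates = {"A": ["ma0", "ma1"], "B": ["mb0", "mb1"]}
        out = ntp_classify(e, templates, n_perm=4000, seed=2, min_genes=2)
        z = e.sub(e.mean(axis=1), axis=0).div(e.std(axis=1, ddof=0), axis=0)
        tvec = {"A": np.array([1, 1, -1, -1]), "B": np.array([-1, -1, 1, 1])}
        for s in e.columns:
            pred = out.loc[s, "predicted"]
            t = tvec[pred]
            d_obs = out.loc[s, "distance"]
            count = 0
            combos = list(itertools.permutations(range(7), 4))
            for pick in combos:
                v = z.iloc[list(pick)][s].to_numpy()
                d = 1 - (t @ v) / (np.linalg.norm(t) * np.linalg.norm(v))
                count += d <= d_obs + 1e-12
            exact = count / len(combos)
            assert out.loc[s, "p"] == pytest.approx(exact, abs=0.05)


class TestSsgsea:
    def test_top_ranked_set_is_maximal_bottom_minimal(self):
        vals = np.arange(10, 0, -1).reshape(-1, 1).astype(float)
        e = expr(vals)
        top = ssgsea_scores(e, {"S": ["g0", "g1"]}).iloc[0, 0]
        bottom = ssgsea_scores(e, {"S": ["g8", "g9"]}).iloc[0, 0]
        for pair in itertools.combinations(range(10), 2):
            s = ssgsea_scores(e, {"S": [f"g{i}" for i in pair]}).iloc[0, 0]
            assert bottom - 1e-9 <= s <= top + 1e-9

    def test_matches_hand_computed_running_sum(self, rng):
        for _ in range(20):
            vals = rng.normal(size=(5, 3))
            e = expr(vals)
            members = ["g1", "g3"]
            got = ssgsea_scores(e, {"S": members})
            for j, s in enumerate(e.columns):
                expected = ssgsea_naive(vals[:, j], [g in members for g in e.index])
                assert got.loc["S", s] == pytest.approx(expected)

    def test_monotone_transform_invariance(self, rng):
        e = expr(rng.normal(size=(30, 6)))
        sets = {"S1": ["g0", "g3", "g7"], "S2": ["g10", "g11"]}
        a = ssgsea_scores(e, sets)
        b = ssgsea_scores(np.exp(e) * 3 + 1, sets)
        pd.testing.assert_frame_equal(a, b)

    def test_sparse_set_rejected(self, rng):
        e = expr(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            ssgsea_scores(e, {"S": ["g0", "missing"]})


class TestAssignSubtype:
    def test_dominant_sample_assigned_and_ties_flagged(self):
        scores = pd.DataFrame(
            {"s0": [5.0, 1.0], "s1": [1.0, 5.0], "s2": [3.0, 3.0]},
            index=["mes", "pro"],
        )
        out = assign_subtype(scores)
        assert out.loc["s0", "subtype"] == "mes"
        assert out.loc["s1", "subtype"] == "pro"

    def test_identical_columns_all_tie_flagged(self):
        scores = pd.DataFrame({"s0": [2.0, 2.0], "s1": [2.0, 2.0]}, index=["a", "b"])
        out = assign_subtype(scores)
        assert out["tie"].all()

    def test_zero_variance_row_normalized_to_zero(self):
        scores = pd.DataFrame(
            {"s0": [1.0, 0.0], "s1": [1.0, 2.0]}, index=["flat", "var"]
        )
        out = assign_subtype(scores)
        assert out.loc["s1", "subtype"] == "var"


class TestGsea:
    def toy(self, rng, planted=True):
        a = rng.normal(0, 1, size=(40, 6))
        if planted:
            a[:8, :3] += 3.0  # first 8 genes up in group a
        e = expr(a)
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=e.columns)
        return e, labels

    def test_planted_set_gets_positive_es_matching_hand_running_sum(self, rng):
        e, labels = self.toy(rng)
        genes = [f"g{i}" for i in range(8)]
        res = gsea_two_class(e, labels, genes, n_perm=200, seed=0)
        assert res.es > 0 and res.p < 0.05
        # recompute the ES by hand on the same ranking
        from gfscan.transcriptome import _signal_to_noise

        metric = _signal_to_noise(e.iloc[:, :3].to_numpy(), e.iloc[:, 3:].to_numpy())
        order = np.argsort(-metric, kind="stable")
        in_set = np.isin(np.arange(40), np.arange(8))[order]
        assert res.es == pytest.approx(gsea_es_naive(metric[order], in_set))

    def test_complement_set_gets_negative_es(self, rng):
        e, labels = self.toy(rng)
        genes = [f"g{i}" for i in range(8, 40)]
        res = gsea_two_class(e, labels, genes, n_perm=100, seed=0)
        assert res.es < 0

    def test_random_sets_give_uniformish_p(self, rng):
        e, labels = self.toy(rng, planted=False)
        ps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            genes = [f"g{i}" for i in r.choice(40, size=8, replace=False)]
            ps.append(gsea_two_class(e, labels, genes, n_perm=100, seed=seed).p)
        assert 0.2 < np.mean(ps) < 0.8
        assert min(ps) > 1 / 101 - 1e-12

    def test_degenerate_metric_rejected(self):
        e = expr(np.ones((20, 6)))
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=e.columns)
        with pytest.raises(ValueError):
            gsea_two_class(e, labels, [f"g{i}" for i in range(6)])
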
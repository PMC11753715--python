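"""Expression filtering, rank/hypergeometric statistics, dosage and bias analyses."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoevolve import dosagex, simdata
from karyoevolve.simdata import ExpressionSimParams


# ---------------------------------------------------------------- oracles
def enum_wilcoxon_p(x, y):
    """Exact two-sided p by full enumeration of all C(n+m, n) rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(x)
    w_obs = ranks[:n].sum()
    mean_w = n * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in combinations(range(len(pooled)), n):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def enum_hypergeom_tail(k, K, n, N, tail):
    """Exact tail by enumeration over draw compositions."""
    total = math.comb(N, n)
    ks = range(k, min(n, K) + 1) if tail == "upper" else range(0, k + 1)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in ks) / total


def sim_expression(dc_mode, seed, n_x=500, n_auto=1500, **kw):
    genes = pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(n_x + n_auto)],
            "stratum": ["anc-X"] * n_x + ["autosome"] * n_auto,
        }
    )
    params = ExpressionSimParams(dc_mode=dc_mode, seed=seed, **kw)
    return simdata.simulate_expression(genes, params)


# ---------------------------------------------------------------- filtering
class TestFilterExpressed:
    @staticmethod
    def _matrix(val_a, val_b):
        matrix = pd.DataFrame(
            {"m_r1": [val_a], "m_r2": [val_a], "f_r1": [val_b], "f_r2": [val_b]},
            index=pd.Index(["g1"], name="gene"),
        )
        samples = pd.DataFrame(
            {
                "sample": ["m_r1", "m_r2", "f_r1", "f_r2"],
                "tissue": ["head_m"] * 2 + ["head_f"] * 2,
                "sex": ["M", "M", "F", "F"],
                "compartment": ["soma"] * 4,
                "replicate": [1, 2, 1, 2],
            }
        )
        return matrix, samples

    @pytest.mark.parametrize(
        "a,b,kept", [(0.5, 0.5, 0), (1.0, 0.0, 1), (0.99, 0.99, 0), (0.0, 5.0, 1)]
    )
    def test_either_sex_rule_is_inclusive_at_one(self, a, b, kept):
        matrix, samples = self._matrix(a, b)
        out, counts = dosagex.filter_expressed(
            matrix, samples, {"sex": "M"}, {"sex": "F"}, min_value=1.0
        )
        assert counts["kept"] == kept == len(out)

    def test_empty_group_rejected(self):
        matrix, samples = self._matrix(1, 1)
        with pytest.raises(ValueError, match="at least one sample"):
            dosagex.filter_expressed(matrix, samples, {"sex": "M"}, {"sex": "Z"})


# ---------------------------------------------------------------- rank test
class TestWilcoxonRankSum:
    def test_worked_example_one_third(self):
        w, p = dosagex.wilcoxon_rank_sum([1.2, 3.4], [5.6, 7.8])
        assert w == 3.0  # ranks 1 + 2
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p = dosagex.wilcoxon_rank_sum([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_mode_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        _, p = dosagex.wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(enum_wilcoxon_p(x, y), abs=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(2, 6), st.integers(2, 6))
    def test_exact_mode_matches_enumeration_small_samples(self, seed, n, m):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=m)
        _, p = dosagex.wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(enum_wilcoxon_p(x, y), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n8(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        _, p_exact = dosagex.wilcoxon_rank_sum(x, y)  # tie-free n=8 -> exact
        # force the approximation with a tie in the pooled sample
        y2 = np.append(y[:-1], x[0])
        _, p_approx = dosagex.wilcoxon_rank_sum(x, y2)
        assert abs(p_approx - enum_wilcoxon_p(x, y2)) < 0.01
        assert abs(p_exact - enum_wilcoxon_p(x, y)) < 1e-12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dosagex.wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------- hypergeometric
class TestHypergeometricTail:
    def test_worked_examples_six_over_252(self):
        assert dosagex.hypergeometric_tail(4, 4, 5, 10, "upper") == pytest.approx(
            6 / 252, abs=1e-12
        )
        assert dosagex.hypergeometric_tail(0, 4, 5, 10, "lower") == pytest.approx(
            6 / 252, abs=1e-12
        )

    def test_degenerate_all_success_upper_tail_is_one(self):
        assert dosagex.hypergeometric_tail(5, 5, 5, 5, "upper") == 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.data())
    def test_matches_enumeration_and_tail_identity(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
        up = dosagex.hypergeometric_tail(k, K, n, N, "upper")
        low = dosagex.hypergeometric_tail(k, K, n, N, "lower")
        assert up == pytest.approx(enum_hypergeom_tail(k, K, n, N, "upper"), abs=1e-12)
        assert low == pytest.approx(enum_hypergeom_tail(k, K, n, N, "lower"), abs=1e-12)
        if k >= 1:
            low_km1 = dosagex.hypergeometric_tail(k - 1, K, n, N, "lower")
            assert up + low_km1 == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            dosagex.hypergeometric_tail(6, 4, 5, 10)


def pair_p_adj(res, a, b):
    pw = res.pairwise
    mask = ((pw["group1"] == a) & (pw["group2"] == b)) | (
        (pw["group1"] == b) & (pw["group2"] == a)
    )
    return float(pw.loc[mask, "p_adj"].iloc[0])


# ---------------------------------------------------------------- dosage compare
class TestDosageCompare:
    @staticmethod
    def _run(dc_mode, seed):
        sim = sim_expression(dc_mode, seed,
                             frac_ovary_biased=0.0, frac_testis_biased=0.0)
        partition = sim.truth.set_index("gene")["stratum"]
        filtered, _ = dosagex.filter_expressed(
            sim.matrix, sim.samples, {"sex": "M", "compartment": "soma"},
            {"sex": "F", "compartment": "soma"},
        )
        return dosagex.dosage_compare(filtered, sim.samples, partition)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_complete_dc_unit_ratio_and_ns_male_contrast(self, seed):
        res = self._run("complete", seed)
        row = res.summary.set_index("stratum").loc["anc-X"]
        assert 0.9 <= row["mf_ratio"] <= 1.1
        assert pair_p_adj(res, ("autosome", "M"), ("anc-X", "M")) >= 0.05

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_no_dc_half_ratio_and_significant_contrast(self, seed):
        res = self._run("none", seed)
        row = res.summary.set_index("stratum").loc["anc-X"]
        assert 0.45 <= row["mf_ratio"] <= 0.55
        assert pair_p_adj(res, ("autosome", "M"), ("anc-X", "M")) < 0.05

    def test_identical_strata_share_one_letter(self):
        rng = np.random.default_rng(0)
        vals = np.tile(rng.lognormal(3, 1, 150), 2)  # strata share one multiset
        matrix = pd.DataFrame(
            {s: vals for s in ("m_r1", "m_r2", "f_r1", "f_r2")},
            index=pd.Index([f"g{i}" for i in range(300)], name="gene"),
        )
        samples = pd.DataFrame(
            {
                "sample": ["m_r1", "m_r2", "f_r1", "f_r2"],
                "tissue": ["head_m"] * 2 + ["head_f"] * 2,
                "sex": ["M", "M", "F", "F"],
                "compartment": ["soma"] * 4,
                "replicate": [1, 2, 1, 2],
            }
        )
        partition = pd.Series(
            ["anc-X" if i < 150 else "autosome" for i in range(300)],
            index=matrix.index,
        )
        res = dosagex.dosage_compare(matrix, samples, partition)
        assert (res.pairwise["p_adj"] >= 0.99).all()
        assert len(set(res.letters.values())) == 1

    def test_row_and_column_order_invariance(self):
        sim = sim_expression("complete", 7, n_x=50, n_auto=100)
        partition = sim.truth.set_index("gene")["stratum"]
        res1 = dosagex.dosage_compare(sim.matrix, sim.samples, partition)
        shuffled = sim.matrix.sample(frac=1.0, random_state=1)[
            list(reversed(sim.matrix.columns))
        ]
        res2 = dosagex.dosage_compare(shuffled, sim.samples, partition)
        pd.testing.assert_frame_equal(res1.summary, res2.summary)


# ---------------------------------------------------------------- proto vs neo
class TestProtoVsNeo:
    def test_identity_outgroup_gives_unit_ratio(self):
        sim = sim_expression("complete", 2, n_x=100, n_auto=100)
        neo = [f"g{i}" for i in range(100)]
        res = dosagex.proto_vs_neo(
            sim.matrix, sim.samples, sim.matrix, sim.samples,
            {g: g for g in neo}, neo,
        )
        assert np.allclose(res["ratio"], 1.0)
        assert (res["p"] > 0.9).all()

    @pytest.mark.parametrize("dc_mode,male_lo,male_hi", [
        ("complete", 0.9, 1.1),
        ("none", 0.4, 0.6),
    ])
    def test_dc_restores_or_halves_ancestral_male_level(self, dc_mode, male_lo, male_hi):
        # outgroup: same genes simulated as autosomal (the proto-X state)
        focal = sim_expression(dc_mode, 2, n_x=300, n_auto=300,
                               frac_ovary_biased=0.0, frac_testis_biased=0.0)
        genes = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(600)], "stratum": ["autosome"] * 600}
        )
        out_params = ExpressionSimParams(seed=2, frac_ovary_biased=0.0,
                                         frac_testis_biased=0.0)
        outgroup = simdata.simulate_expression(genes, out_params)
        neo = focal.truth.loc[focal.truth.stratum == "anc-X", "gene"].tolist()
        res = dosagex.proto_vs_neo(
            focal.matrix, focal.samples, outgroup.matrix, outgroup.samples,
            {g: g for g in neo}, neo,
        ).set_index(["sex", "compartment"])
        assert male_lo <= res.loc[("M", "soma"), "ratio"] <= male_hi
        assert 0.9 <= res.loc[("F", "soma"), "ratio"] <= 1.1

    def test_unmappable_set_rejected(self):
        sim = sim_expression("complete", 1, n_x=10, n_auto=10)
        with pytest.raises(ValueError, match="mapped"), pytest.warns(UserWarning):
            dosagex.proto_vs_neo(
                sim.matrix, sim.samples, sim.matrix, sim.samples, {}, ["g1"]
            )


# ---------------------------------------------------------------- gonad bias
def bias_fixture(ovary, testis, head_m, head_f):
    matrix = pd.DataFrame(
        {
            "ovary_r1": [ovary], "ovary_r2": [ovary],
            "testis_r1": [testis], "testis_r2": [testis],
            "head_m_r1": [head_m], "head_m_r2": [head_m],
            "head_f_r1": [head_f], "head_f_r2": [head_f],
        },
        index=pd.Index(["g1"], name="gene"),
    )
    samples = pd.DataFrame(
        {
            "sample": matrix.columns,
            "tissue": ["ovary"] * 2 + ["testis"] * 2 + ["head_m"] * 2 + ["head_f"] * 2,
            "sex": ["F", "F", "M", "M", "M", "M", "F", "F"],
            "compartment": ["gonad"] * 4 + ["soma"] * 4,
            "replicate": [1, 2] * 4,
        }
    )
    return matrix, samples


class TestGonadBias:
    @pytest.mark.parametrize(
        "ovary,testis,head_m,head_f,expected",
        [
            (10.0, 4.9, 4.0, 4.0, "ovary"),     # 10 > 2 x 4.9
            (10.0, 5.0, 4.0, 4.0, "none"),      # exactly 2-fold: strict rule
            (0.0, 0.0, 0.0, 0.0, "none"),       # all-zero gene
            (3.0, 20.0, 9.0, 2.0, "testis"),
        ],
    )
    def test_strict_two_fold_rule(self, ovary, testis, head_m, head_f, expected):
        matrix, samples = bias_fixture(ovary, testis, head_m, head_f)
        calls = dosagex.classify_gonad_bias(matrix, samples, fold=2.0)
        assert calls["g1"] == expected

    def test_missing_gonad_tissue_rejected(self):
        matrix, samples = bias_fixture(1, 1, 1, 1)
        soma_only = samples[samples.compartment == "soma"]
        with pytest.raises(ValueError, match="ovary and .* testis"):
            dosagex.classify_gonad_bias(matrix[soma_only["sample"]], soma_only)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recall_and_precision_on_simulated_truth(self, seed):
        sim = sim_expression("complete", seed, n_x=0, n_auto=2000,
                             frac_ovary_biased=0.1, frac_testis_biased=0.1,
                             bias_fold=4.0, noise_log_sd=0.2)
        calls = dosagex.classify_gonad_bias(sim.matrix, sim.samples, fold=2.0)
        truth = sim.truth.set_index("gene")["bias"].replace({"none": "none"})
        for cls in ("ovary", "testis"):
            tp = ((calls == cls) & (truth == cls)).sum()
            recall = tp / (truth == cls).sum()
            precision = tp / (calls == cls).sum()
            assert recall >= 0.95 and precision >= 0.95


# ---------------------------------------------------------------- enrichment
class TestEnrichment:
    def test_background_proportions_are_ns(self):
        # per 40-gene block: 10 anc-X genes (1 ovary-biased) and 30 autosomal
        # (3 ovary-biased) -> both strata exactly at the 10% background rate
        genes = [f"g{i}" for i in range(400)]
        part, calls = [], []
        for i in range(400):
            j = i % 40
            part.append("anc-X" if j < 10 else "autosome")
            calls.append("ovary" if j in (0, 10, 11, 12) else "none")
        res = dosagex.test_enrichment(
            pd.Series(calls, index=genes), pd.Series(part, index=genes)
        )
        assert (res["verdict"] == "ns").all()

    def test_toy_counts_match_hypergeometric_oracle(self):
        genes = [f"g{i}" for i in range(10)]
        calls = pd.Series(["ovary"] * 4 + ["none"] * 6, index=genes)
        part = pd.Series(["anc-X"] * 4 + ["autosome"] * 5 + ["anc-X"], index=genes)
        res = dosagex.test_enrichment(calls, part, min_genes=1)
        row = res.set_index(["stratum", "bias_class"]).loc[("anc-X", "ovary")]
        assert row["p_enrichment"] == pytest.approx(6 / 252, abs=1e-12)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_depleted_testis_fraction_detected(self, seed):
        rng = np.random.default_rng(seed)
        n_x, n_auto = 500, 4500
        genes = [f"g{i}" for i in range(n_x + n_auto)]
        part = pd.Series(["anc-X"] * n_x + ["autosome"] * n_auto, index=genes)
        frac = np.where(np.arange(n_x + n_auto) < n_x, 0.02, 0.10)
        calls = pd.Series(
            np.where(rng.random(n_x + n_auto) < frac, "testis", "none"), index=genes
        )
        res = dosagex.test_enrichment(calls, part)
        row = res.set_index(["stratum", "bias_class"]).loc[("anc-X", "testis")]
        assert row["verdict"] == "depleted"

    def test_empty_bias_class_is_ns_with_p_one(self):
        genes = [f"g{i}" for i in range(100)]
        calls = pd.Series(["none"] * 100, index=genes)
        part = pd.Series(["anc-X"] * 50 + ["autosome"] * 50, index=genes)
        res = dosagex.test_enrichment(calls, part)
        up = res.set_index(["stratum", "bias_class"]).loc[("anc-X", "ovary")]
        assert up["p_enrichment"] == 1.0 and up["verdict"] == "ns"
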
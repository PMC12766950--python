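import numpy as np
import pandas as pd
import pytest

from wntaxis import screen, stats
from wntaxis.io_formats import ExpressionMatrix
from wntaxis.screen import (
    binary_cluster,
    eligible_tissues,
    mean_target_expression,
    positive_tissue_count,
    q1_vs_q4_test,
    quartile_stratify,
    run_screen,
    spearman_screen,
)
from wntaxis.simulate import ScreenSimConfig, simulate_cell_line_matrix


def _matrix(values: dict, tissues: dict) -> ExpressionMatrix:
    df = pd.DataFrame(values).T
    return ExpressionMatrix(values=df, sample_tissue=pd.Series(tissues))


class TestQuartiles:
    def test_eight_samples_hand_assignment(self):
        vals = pd.Series({f"s{i}": float(i) for i in range(1, 9)})
        qa = quartile_stratify(vals)
        assert set(qa.index[qa == "Q1"]) == {"s8", "s7"}
        assert set(qa.index[qa == "Q4"]) == {"s1", "s2"}

    def test_n10_sizes_3322(self):
        vals = pd.Series({f"s{i:02d}": float(i) for i in range(10)})
        qa = quartile_stratify(vals)
        assert qa.value_counts().to_dict() == {"Q1": 3, "Q2": 3, "Q3": 2, "Q4": 2}
        # highest three values land in Q1
        assert set(qa.index[qa == "Q1"]) == {"s09", "s08", "s07"}

    def test_tie_break_by_sample_id_is_stable(self):
        vals = pd.Series({"b": 1.0, "a": 1.0, "d": 1.0, "c": 1.0})
        qa = quartile_stratify(vals)
        assert qa["a"] == "Q1" and qa["b"] == "Q2" and qa["c"] == "Q3" and qa["d"] == "Q4"

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            quartile_stratify(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))


class TestQ1Q4:
    def test_exact_p_is_one_over_c63(self):
        # 8 samples: Q1 = top 2, Q4 = bottom 2; target perfectly aligned
        ids = [f"s{i}" for i in range(1, 9)]
        sig = pd.Series(dict(zip(ids, map(float, range(1, 9)))))
        target = pd.Series(dict(zip(ids, map(float, range(1, 9)))))
        qa = quartile_stratify(sig)
        res = q1_vs_q4_test(target, qa, exact=True)
        # both Q1 targets above both Q4 targets: p = 1 / C(4,2) = 1/6
        assert res.p_value == pytest.approx(1 / 6)

    def test_anti_aligned_target_not_significant(self):
        ids = [f"s{i}" for i in range(1, 11)]
        sig = pd.Series(dict(zip(ids, map(float, range(1, 11)))))
        target = pd.Series(dict(zip(ids, map(float, range(10, 0, -1)))))
        res = q1_vs_q4_test(target, quartile_stratify(sig), exact=True)
        assert res.p_value > 0.9


class TestEligibility:
    def _em_with_counts(self, n_per_tissue):
        samples, tissues = [], {}
        for t, n in n_per_tissue.items():
            for i in range(n):
                s = f"{t}_{i:02d}"
                samples.append(s)
                tissues[s] = t
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.uniform(0, 5, size=(2, len(samples))), index=["WNT7B", "G1"], columns=samples
        )
        return ExpressionMatrix(values=values, sample_tissue=pd.Series(tissues))

    def test_strictly_more_than_min_lines(self):
        em = self._em_with_counts({"t20": 20, "t21": 21, "t19": 19})
        assert eligible_tissues(em, min_lines=20) == ["t21"]

    def test_boundary_both_sides(self):
        em = self._em_with_counts({"a": 21, "b": 20})
        assert eligible_tissues(em, min_lines=20) == ["a"]
        assert set(eligible_tissues(em, min_lines=19)) == {"a", "b"}


class TestSpearmanScreen:
    @pytest.fixture()
    def em(self):
        rng = np.random.default_rng(3)
        n = 25
        samples = [f"s{i:02d}" for i in range(n)]
        target = rng.normal(size=n)
        values = pd.DataFrame(
            {
                "WNT7B": target,
                "SELF": target,  # identical to target
                "ANTI": -target,
                "NOISE": rng.normal(size=n),
                "CONST": np.ones(n),
            }
        ).T
        values.columns = samples
        values = values - values.min().min()  # keep non-negative
        return ExpressionMatrix(
            values=values, sample_tissue=pd.Series(["t1"] * n, index=samples)
        )

    def test_self_correlation_is_one(self, em):
        res = spearman_screen(em, ["SELF", "ANTI"], "WNT7B", min_lines=20)
        t = res.table.set_index("gene")
        assert t.loc["SELF", "rho"] == pytest.approx(1.0)
        assert t.loc["ANTI", "rho"] == pytest.approx(-1.0)
        assert not t.loc["SELF", "masked"]

    def test_constant_gene_nan_and_masked(self, em):
        res = spearman_screen(em, ["CONST"], "WNT7B", min_lines=20)
        row = res.table.iloc[0]
        assert np.isnan(row["rho"]) and bool(row["masked"])

    def test_missing_gene_recorded_as_nan(self, em):
        res = spearman_screen(em, ["SELF", "ABSENT"], "WNT7B", min_lines=20)
        row = res.table.set_index("gene").loc["ABSENT"]
        assert np.isnan(row["rho"]) and bool(row["masked"])

    def test_all_genes_missing_rejected(self, em):
        with pytest.raises(ValueError, match="no signature gene"):
            spearman_screen(em, ["ABSENT"], "WNT7B", min_lines=20)

    def test_monotone_transform_invariance(self, em):
        res1 = spearman_screen(em, ["NOISE"], "WNT7B", min_lines=20)
        em2 = ExpressionMatrix(
            values=np.exp(em.values / 4.0), sample_tissue=em.sample_tissue
        )
        res2 = spearman_screen(em2, ["NOISE"], "WNT7B", min_lines=20)
        assert res1.table["rho"].iloc[0] == pytest.approx(res2.table["rho"].iloc[0])
        assert res1.table["rho_p"].iloc[0] == pytest.approx(res2.table["rho_p"].iloc[0])

    def test_vectorised_block_matches_scalar_spearman(self, rng):
        n = 30
        block = rng.normal(size=(8, n))
        tv = rng.normal(size=n)
        rho_vec, p_vec = screen._spearman_tissue_block(block, tv)
        for i in range(8):
            ref = stats.spearman(block[i], tv)
            assert rho_vec[i] == pytest.approx(ref.statistic)
            assert p_vec[i] == pytest.approx(ref.p_value, rel=1e-9)

    def test_bh_masking_is_more_conservative(self, em):
        raw = spearman_screen(em, ["SELF", "ANTI", "NOISE"], "WNT7B", min_lines=20)
        adj = spearman_screen(
            em, ["SELF", "ANTI", "NOISE"], "WNT7B", min_lines=20, adjust="bh"
        )
        assert (adj.table["mask_p"] >= raw.table["mask_p"] - 1e-12).all()


class TestBinaryCluster:
    def _result_from_binary(self, binary: dict[str, list[int]], tissues: list[str]):
        rows = []
        for g, profile in binary.items():
            for t, sig in zip(tissues, profile):
                rows.append(
                    {
                        "tissue": t,
                        "gene": g,
                        "rho": 0.5 if sig else 0.0,
                        "rho_p": 0.01 if sig else 0.5,
                        "mask_p": 0.01 if sig else 0.5,
                        "masked": not sig,
                        "q1q4_p": np.nan,
                    }
                )
        return screen.TissueScreenResult(table=pd.DataFrame(rows), target_gene="WNT7B")

    def test_pair_distance_two_thirds_grouping(self):
        # hand computation: d(A,B)=2/3, d(A,C)=d(B,C)=1 -> A and B join first
        res = self._result_from_binary(
            {"A": [1, 1, 0], "B": [1, 0, 1], "C": [0, 0, 0]}, ["t1", "t2", "t3"]
        )
        order = binary_cluster(res)
        assert order.index("C") in (0, 2)
        ia, ib = order.index("A"), order.index("B")
        assert abs(ia - ib) == 1

    def test_five_gene_hand_dendrogram(self):
        # two tight groups: {A, B} identical, {D, E} identical, C all-zero.
        res = self._result_from_binary(
            {
                "A": [1, 1, 0, 0],
                "B": [1, 1, 0, 0],
                "D": [0, 0, 1, 1],
                "E": [0, 0, 1, 1],
                "C": [0, 0, 0, 0],
            },
            ["t1", "t2", "t3", "t4"],
        )
        order = binary_cluster(res)
        pos = {g: order.index(g) for g in "ABCDE"}
        assert abs(pos["A"] - pos["B"]) == 1
        assert abs(pos["D"] - pos["E"]) == 1

    def test_single_gene_passthrough(self):
        res = self._result_from_binary({"A": [1, 0]}, ["t1", "t2"])
        assert binary_cluster(res) == ["A"]

    def test_all_zero_pair_distance_zero_keeps_clustering_total(self):
        res = self._result_from_binary(
            {"Z1": [0, 0], "Z2": [0, 0], "S": [1, 1]}, ["t1", "t2"]
        )
        order = binary_cluster(res)
        assert sorted(order) == ["S", "Z1", "Z2"]
        assert abs(order.index("Z1") - order.index("Z2")) == 1


@pytest.fixture(scope="module")
def screened():
    cfg = ScreenSimConfig(
        n_tissues=12,
        lines_per_tissue=30,
        n_signature_genes=10,
        n_null_genes=20,
        planted_rho=0.7,
        planted_tissue_fraction=0.5,
        seed=17,
    )
    em, truth = simulate_cell_line_matrix(cfg)
    genes = truth.attrs["signature_genes"] + truth.attrs["null_genes"]
    res = run_screen(em, genes, "WNT7B", min_lines=20, min_tissues=5)
    return res, truth


class TestEndToEndRecovery:
    def test_planted_genes_flagged_nulls_not(self, screened):
        res, truth = screened
        flagged = set(res.flagged_genes)
        assert set(truth.attrs["signature_genes"]) <= flagged
        assert not (set(truth.attrs["null_genes"]) & flagged)

    def test_positive_counts_bounded_by_tissues(self, screened):
        res, truth = screened
        n_eligible = res.table["tissue"].nunique()
        assert (res.positive_counts <= n_eligible).all()
        assert (res.positive_counts >= 0).all()

    def test_planted_genes_form_contiguous_leaf_block(self, screened):
        res, truth = screened
        pos = [res.gene_order.index(g) for g in truth.attrs["signature_genes"]]
        assert max(pos) - min(pos) == len(pos) - 1

    def test_mean_target_present_for_all_eligible_tissues(self, screened):
        res, _ = screened
        assert set(res.mean_target.index) == set(res.table["tissue"].unique())
        assert (res.mean_target > 0).all()


def test_mean_target_requires_gene(tiny_expression):
    with pytest.raises(ValueError):
        mean_target_expression(tiny_expression, "NOPE", min_lines=5)


def test_positive_tissue_count_threshold_is_inclusive():
    rows = []
    for t in range(5):
        rows.append(
            {
                "tissue": f"t{t}",
                "gene": "G",
                "rho": 0.4,
                "rho_p": 0.01,
                "mask_p": 0.01,
                "masked": False,
                "q1q4_p": np.nan,
            }
        )
    res = screen.TissueScreenResult(table=pd.DataFrame(rows), target_gene="WNT7B")
    counts, flagged = positive_tissue_count(res, min_tissues=5)
    assert counts["G"] == 5
    assert flagged == ["G"]  # exactly 5 positive tissues is enough
    counts, flagged = positive_tissue_count(res, min_tissues=6)
    assert flagged == []
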
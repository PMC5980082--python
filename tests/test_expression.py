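import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wrkyscan.expression import (
    ContrastError,
    NormalizationError,
    cluster_genes,
    contrast_matrix,
    ddct,
    dendrogram_newick,
    direction_counts,
)
from wrkyscan.seq_io import CtTable, ExpressionMatrix
from wrkyscan.synthetic import SyntheticSpec, make_ct, make_expression


def ct_table(rows):
    return CtTable(pd.DataFrame(rows))


def simple_ct(target_shift=0.0, ref_shift=0.0):
    rows = []
    for sample, t_extra, r_extra in [("cal", 0.0, 0.0),
                                     ("s1", target_shift, ref_shift)]:
        for _ in range(3):
            rows.append(dict(sample=sample, gene="ref", ct=20.0 + r_extra))
            rows.append(dict(sample=sample, gene="tgt", ct=24.0 + t_extra))
    return ct_table(rows)


class TestDdct:
    def test_calibrator_maps_to_exactly_one(self):
        results = ddct(simple_ct(), "tgt", "ref", "cal")
        by_sample = {r.sample: r for r in results}
        assert by_sample["cal"].relative_expression == 1.0

    def test_ddct_minus_two_gives_fourfold(self):
        results = ddct(simple_ct(target_shift=-2.0), "tgt", "ref", "cal")
        by_sample = {r.sample: r for r in results}
        assert by_sample["s1"].relative_expression == pytest.approx(4.0)

    def test_target_shift_plus_one_halves_expression(self):
        results = ddct(simple_ct(target_shift=1.0), "tgt", "ref", "cal")
        by_sample = {r.sample: r for r in results}
        assert by_sample["s1"].relative_expression == pytest.approx(0.5)

    def test_missing_reference_wells_error(self):
        rows = [dict(sample="cal", gene="ref", ct=20.0),
                dict(sample="cal", gene="tgt", ct=24.0),
                dict(sample="s1", gene="tgt", ct=24.0)]
        with pytest.raises(NormalizationError, match="ref"):
            ddct(ct_table(rows), "tgt", "ref", "cal")

    def test_missing_calibrator_error(self):
        with pytest.raises(NormalizationError, match="nope"):
            ddct(simple_ct(), "tgt", "ref", "nope")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift=st.floats(-5, 5, allow_nan=False))
    def test_invariant_to_constant_ct_shift_per_sample(self, shift):
        base = ddct(simple_ct(target_shift=-1.0), "tgt", "ref", "cal")
        shifted_rows = simple_ct(target_shift=-1.0).data.copy()
        shifted_rows.loc[shifted_rows["sample"] == "s1", "ct"] += shift
        shifted = ddct(CtTable(shifted_rows), "tgt", "ref", "cal")
        for a, b in zip(base, shifted):
            assert a.relative_expression == pytest.approx(
                b.relative_expression
            )


class TestContrastMatrix:
    def mat(self, values, mask=None):
        df = pd.DataFrame(values, dtype=float)
        return ExpressionMatrix(
            values=df, mask=None if mask is None else pd.DataFrame(mask)
        )

    def test_equal_columns_all_unchanged(self):
        m = self.mat({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        results = contrast_matrix(m, {"c": ("a", "b")})
        assert {r.direction for r in results} == {"unchanged"}

    def test_fourfold_gene_up(self):
        m = self.mat({"trt": [4.0], "ctl": [2.0]})
        (r,) = contrast_matrix(m, {"c": ("trt", "ctl")})
        assert r.log2fc == pytest.approx(2.0)
        assert r.direction == "up"

    def test_masked_gene_flagged_missing(self):
        m = self.mat({"a": [np.nan, 1.0], "b": [0.0, 0.0]})
        results = contrast_matrix(m, {"c": ("a", "b")})
        assert results[0].direction == "missing" and results[0].missing

    def test_unknown_column_config_error(self):
        m = self.mat({"a": [1.0]})
        with pytest.raises(ContrastError, match="nope"):
            contrast_matrix(m, {"c": ("a", "nope")})

    def test_threshold_gates_direction(self):
        m = self.mat({"a": [0.5, -0.5], "b": [0.0, 0.0]})
        results = contrast_matrix(m, {"c": ("a", "b")}, lfc_threshold=0.4)
        assert [r.direction for r in results] == ["up", "down"]


class TestDirectionCounts:
    def test_all_unchanged(self):
        m = pd.DataFrame({"a": [0.0] * 5, "b": [0.0] * 5}, dtype=float)
        results = contrast_matrix(ExpressionMatrix(values=m), {"c": ("a", "b")})
        tab = direction_counts(results)
        assert tab.loc["c"].tolist() == [0, 0, 5, 0]

    def test_planted_direction_fractions_recovered_at_zero_noise(self, rng):
        spec = SyntheticSpec(expression_noise_sd=0.0, mask_fraction=0.0)
        expr, truth = make_expression(spec, rng)
        results = contrast_matrix(
            expr,
            {"MeJA-vs-control": ("MeJA", "control"),
             "GA-vs-control": ("GA", "control"),
             "NA-vs-CA": ("NA", "CA")},
        )
        tab = direction_counts(results)
        for contrast in truth.columns:
            assert tab.loc[contrast, "up"] == (truth[contrast] > 0).sum()
            assert tab.loc[contrast, "down"] == (truth[contrast] < 0).sum()

    def test_tallies_conserve_gene_count(self, rng):
        expr, _ = make_expression(SyntheticSpec(), rng)
        results = contrast_matrix(
            expr, {"NA-vs-CA": ("NA", "CA")}
        )
        tab = direction_counts(results)
        assert tab.sum(axis=1).unique().tolist() == [len(expr.genes)]

    def test_fully_masked_gene_counted_missing_only(self):
        values = pd.DataFrame({"a": [np.nan, 0.0], "b": [np.nan, 0.0]},
                              dtype=float)
        results = contrast_matrix(
            ExpressionMatrix(values=values), {"c": ("a", "b")}
        )
        tab = direction_counts(results)
        assert tab.loc["c", "missing"] == 1


class TestClusterGenes:
    def mat(self, arr, index):
        return ExpressionMatrix(
            values=pd.DataFrame(arr, index=index, dtype=float)
        )

    def test_identical_pair_merges_first(self):
        m = self.mat([[0, 0], [0, 0], [10, 10]], ["g1", "g2", "g3"])
        res = cluster_genes(m)
        # first linkage row merges rows 0 and 1 at height 0
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}
        assert res.linkage[0, 2] == 0.0

    def test_permuting_rows_same_dendrogram_up_to_relabeling(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(6, 4))
        genes = [f"g{i}" for i in range(6)]
        m1 = self.mat(arr, genes)
        perm = rng.permutation(6)
        m2 = self.mat(arr[perm], [genes[i] for i in perm])
        r1, r2 = cluster_genes(m1), cluster_genes(m2)
        order2 = r2.gene_order
        assert r1.gene_order in (order2, order2[::-1]) or set(
            r1.gene_order
        ) == set(order2)
        # merge heights identical regardless of row order
        assert np.allclose(sorted(r1.linkage[:, 2]), sorted(r2.linkage[:, 2]))

    def test_missing_rows_dropped_by_default_imputed_behind_flag(self):
        values = pd.DataFrame(
            [[0.0, np.nan], [1.0, 1.0], [2.0, 2.0]],
            index=["g1", "g2", "g3"], dtype=float,
        )
        m = ExpressionMatrix(values=values)
        res = cluster_genes(m)
        assert res.genes_dropped == ["g1"]
        res2 = cluster_genes(m, impute_zero=True)
        assert res2.genes_dropped == []
        assert len(res2.genes_used) == 3

    def test_fewer_than_two_usable_rows_errors(self):
        values = pd.DataFrame([[0.0], [np.nan]], index=["g1", "g2"],
                              dtype=float)
        with pytest.raises(ValueError):
            cluster_genes(ExpressionMatrix(values=values))

    def test_dendrogram_newick_parses(self):
        from wrkyscan import phylogeny as phy

        m = self.mat([[0, 0], [1, 1], [5, 5], [6, 6]],
                     ["g1", "g2", "g3", "g4"])
        nwk = dendrogram_newick(cluster_genes(m))
        tree = phy.read_newick(nwk)
        assert sorted(tree.leaf_labels()) == ["g1", "g2", "g3", "g4"]


class TestCtRecovery:
    def test_noise_free_ct_recovers_planted_fold_changes_exactly(self, rng):
        spec = SyntheticSpec(ct_noise_sd=0.0)
        ct, truth = make_ct(spec, rng)
        for gene in spec.ct_plan:
            treatments = {t for (t, _) in spec.ct_plan[gene]}
            for treatment in treatments:
                cal = f"{treatment}_0h"
                results = ddct(ct, gene, "Actin", cal)
                for r in results:
                    if (gene, r.sample) in truth and r.sample.startswith(
                        treatment
                    ):
                        assert r.relative_expression == pytest.approx(
                            truth[(gene, r.sample)], rel=1e-9
                        )
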
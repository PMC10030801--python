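"""Correspondence analysis (vs. brute-force oracle), optimal codons, clustering."""

import io

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from codonforge.coa_optimal import (
    axis_correlations,
    coa_on_rscu,
    high_frequency_codons,
    optimal_codons,
    rscu_cluster,
    rscu_matrix_from_genes,
    select_extreme_genes,
)
from codonforge.codon_statistics import CodonCountTable, count_codons, pooled_counts, rscu
from codonforge.expression_indices import UsageIndexRecord, cai, cai_weights
from codonforge.sequence_io import GeneSet

from conftest import make_gene, random_cds


def ca_inertia_oracle(n: np.ndarray) -> np.ndarray:
    """Eigenvalues of the chi-square residual cross-product, largest first."""
    p = n / n.sum()
    r, c = p.sum(axis=1), p.sum(axis=0)
    s = np.zeros_like(p, dtype=float)
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            s[i, j] = (p[i, j] - r[i] * c[j]) / np.sqrt(r[i] * c[j])
    ev = np.linalg.eigvalsh(s @ s.T)[::-1]
    return ev[: min(n.shape) - 1]


class TestCorrespondenceAnalysis:
    def test_inertias_match_bruteforce_eigendecomposition(self, rng):
        for _ in range(10):
            n = rng.integers(1, 40, size=(3, 4)).astype(float)
            df = pd.DataFrame(n, index=list("abc"), columns=list("wxyz"))
            res = coa_on_rscu(df)
            want = ca_inertia_oracle(n)
            assert np.max(np.abs(res.inertias - want[: res.n_axes])) < 1e-10

    def test_total_inertia_equals_chi2_over_grand_total(self, rng):
        from scipy.stats import chi2_contingency

        n = rng.integers(1, 30, size=(5, 6)).astype(float)
        res = coa_on_rscu(pd.DataFrame(n))
        chi2 = chi2_contingency(n, correction=False)[0]
        assert res.total_inertia == pytest.approx(chi2 / n.sum())

    def test_identical_rows_have_zero_inertia(self):
        df = pd.DataFrame([[1, 2, 3, 4]] * 3, index=list("abc"))
        with pytest.warns(UserWarning, match="rank"):
            res = coa_on_rscu(df)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-14)
        assert np.isnan(res.contribution_pct).all()

    def test_row_permutation_invariance(self, rng):
        n = rng.integers(1, 30, size=(4, 5)).astype(float)
        df = pd.DataFrame(n, index=list("abcd"))
        perm = df.loc[list("cadb")]
        r1, r2 = coa_on_rscu(df), coa_on_rscu(perm)
        assert np.allclose(r1.inertias, r2.inertias)
        assert np.allclose(
            r1.row_coords.loc[list("abcd")].values,
            r2.row_coords.loc[list("abcd")].values,
        )

    def test_contributions_sum_to_100(self, rng):
        n = rng.integers(1, 30, size=(5, 8)).astype(float)
        res = coa_on_rscu(pd.DataFrame(n))
        assert res.contribution_pct.sum() == pytest.approx(100.0)

    def test_zero_sum_columns_dropped_with_warning(self):
        df = pd.DataFrame([[1, 2, 0], [3, 1, 0], [2, 2, 0]], columns=list("xyz"))
        with pytest.warns(UserWarning, match="zero-sum"):
            res = coa_on_rscu(df)
        assert res.dropped_cols == ("z",)

    def test_reconstruction_identity_within_rank(self, rng):
        # P = r c^T (1 + sum_k F_k G_k^T / sqrt(lambda_k)) on a full-rank toy
        n = rng.integers(1, 20, size=(3, 4)).astype(float)
        df = pd.DataFrame(n)
        res = coa_on_rscu(df)
        p = n / n.sum()
        r, c = p.sum(axis=1), p.sum(axis=0)
        f, g = res.row_coords.values, res.col_coords.values
        lam = res.inertias
        recon = np.outer(r, c) * (1 + (f / np.sqrt(lam)) @ g.T)
        assert np.allclose(recon, p, atol=1e-12)


class TestAxisCorrelations:
    def _gene_set_with_gradient(self, rng):
        # genes along a GC3 gradient: Axis 1 should align with GC3s
        genes = []
        for i, g3 in enumerate(np.linspace(0.05, 0.9, 8)):
            from codonforge.synthetic_data import SimSpec, _draw_gene

            spec = SimSpec(gc3_pressure=float(g3), seed=i)
            seq = _draw_gene(spec, 400, np.random.default_rng(100 + i))
            from codonforge.sequence_io import CodingSequence

            genes.append(CodingSequence("sp", f"g{i}", seq, has_terminal_stop=True))
        return GeneSet(species="sp", genes=genes)

    def test_indicator_equal_to_axis_has_r_one(self, rng):
        n = rng.integers(1, 30, size=(6, 8)).astype(float)
        res = coa_on_rscu(pd.DataFrame(n, index=[f"g{i}" for i in range(6)]))
        recs = [
            UsageIndexRecord(species="sp", gene=f"g{i}",
                             values={"ind": res.row_coords["Axis1"].iloc[i]})
            for i in range(6)
        ]
        df = axis_correlations(res, recs, ["ind"])
        assert df.iloc[0]["r"] == pytest.approx(1.0)

    def test_misaligned_labels_error(self, rng):
        n = rng.integers(1, 30, size=(4, 5)).astype(float)
        res = coa_on_rscu(pd.DataFrame(n, index=list("abcd")))
        recs = [UsageIndexRecord(species="sp", gene="zzz", values={"ind": 1.0})]
        with pytest.raises(ValueError, match="missing"):
            axis_correlations(res, recs, ["ind"])

    def test_gc3_gradient_loads_on_axis_one(self, rng, code):
        gs = self._gene_set_with_gradient(rng)
        mat = rscu_matrix_from_genes(gs)
        res = coa_on_rscu(mat)
        from codonforge.codon_statistics import synonymous_third_position_stats

        recs = []
        for g in gs:
            third = synonymous_third_position_stats(count_codons(g), code)
            recs.append(UsageIndexRecord(species="sp", gene=g.gene,
                                         values={"GC3s": third["GC3s"]}))
        df = axis_correlations(res, recs, ["GC3s"])
        assert abs(df.iloc[0]["r"]) > 0.8


class TestHighFrequencyCodons:
    def test_uniform_usage_yields_empty_set(self, code):
        counts = {c: 2 for c in code.synonymous_codons}
        t = rscu(CodonCountTable(counts=counts), code)
        assert high_frequency_codons(t) == frozenset()

    def test_strict_threshold(self, code):
        t = rscu(CodonCountTable(counts={"AAA": 3, "AAG": 1}), code)
        assert high_frequency_codons(t) == {"AAA"}


class TestOptimalCodons:
    def _set_of(self, n):
        rng = np.random.default_rng(77)
        genes = [random_cds(rng, 150, gene=f"g{i:02d}") for i in range(n)]
        return GeneSet(species="sp", genes=genes)

    def test_twelve_genes_select_two_per_end(self):
        gs = self._set_of(12)
        cai_vals = {f"g{i:02d}": 0.9 - 0.05 * i for i in range(12)}
        rep = optimal_codons(gs, cai_vals)
        assert len(rep.high_genes) == 2 and len(rep.low_genes) == 2
        assert rep.high_genes == ("g00", "g01")
        assert rep.low_genes == ("g10", "g11")

    def test_identical_usage_yields_no_optimal_codons(self, code):
        genes = [make_gene(["AAA", "AAG"] * 60, gene=f"g{i}") for i in range(10)]
        gs = GeneSet(species="sp", genes=genes)
        rep = optimal_codons(gs, {f"g{i}": 1.0 - 0.01 * i for i in range(10)})
        assert all(abs(d) < 1e-12 for d in rep.delta_rscu.values())
        assert rep.optimal == frozenset()

    def test_planted_codon_recovered(self, code):
        # high-CAI genes use AAA:AAG 3:1, low-CAI genes 1:3; full-set RSCU(AAA)>1
        high = [make_gene(["AAA"] * 90 + ["AAG"] * 30, gene=f"h{i}") for i in range(2)]
        mid = [make_gene(["AAA"] * 66 + ["AAG"] * 54, gene=f"m{i}") for i in range(8)]
        low = [make_gene(["AAA"] * 30 + ["AAG"] * 90, gene=f"l{i}") for i in range(2)]
        gs = GeneSet(species="sp", genes=high + mid + low)
        cai_vals = {g.gene: v for g, v in zip(high + mid + low, np.linspace(1, 0.1, 12))}
        rep = optimal_codons(gs, cai_vals)
        # Delta-RSCU(AAA) = 2*(3/4) - 2*(1/4) = 1.0
        assert rep.delta_rscu["AAA"] == pytest.approx(1.0)
        assert rep.rscu_full["AAA"] > 1.0
        assert "AAA" in rep.optimal
        assert "AAG" not in rep.optimal

    def test_every_optimal_codon_passes_both_thresholds(self):
        gs = self._set_of(12)
        wts = cai_weights(gs)
        cai_vals = {g.gene: cai(count_codons(g), wts) for g in gs}
        rep = optimal_codons(gs, cai_vals)
        assert rep.optimal <= rep.high_frequency
        assert rep.optimal <= rep.high_expression
        for c in rep.optimal:
            assert rep.delta_rscu[c] > 0.08
            assert rep.rscu_full[c] > 1.0

    def test_gene_order_invariance(self):
        gs = self._set_of(12)
        cai_vals = {f"g{i:02d}": 0.9 - 0.05 * i for i in range(12)}
        rep1 = optimal_codons(gs, cai_vals)
        shuffled = GeneSet(species="sp", genes=list(reversed(gs.genes)), code=gs.code)
        rep2 = optimal_codons(shuffled, cai_vals)
        assert rep1.optimal == rep2.optimal
        assert rep1.high_genes == rep2.high_genes

    def test_cai_ties_broken_lexicographically(self):
        labels = [f"g{i}" for i in range(5)]
        high, low = select_extreme_genes(labels, {g: 0.5 for g in labels}, frac=0.2)
        assert high == ["g0"] and low == ["g4"]


class TestRscuCluster:
    def _matrix(self, rows, labels):
        return pd.DataFrame(rows, index=labels)

    def test_two_species_single_merge(self):
        tree = rscu_cluster(self._matrix([[1, 0, 2], [0, 1, 2]], ["a", "b"]))
        assert tree.linkage_matrix.shape == (1, 4)
        assert tree.newick.count(",") == 1

    def test_identical_rows_merge_first_at_zero_height(self):
        m = self._matrix([[1, 2, 3], [1, 2, 3], [9, 9, 9]], ["a", "b", "c"])
        tree = rscu_cluster(m)
        assert tree.linkage_matrix[0, 2] == pytest.approx(0.0)
        d = tree.cophenetic_distances()
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_planted_two_block_structure_recovered(self):
        m = self._matrix(
            [[0, 0, 0.1], [0.1, 0, 0], [10, 10, 10.1], [10.1, 10, 10]],
            ["a1", "a2", "b1", "b2"],
        )
        tree = rscu_cluster(m)
        d = tree.cophenetic_distances()
        assert d.loc["a1", "a2"] < d.loc["a1", "b1"]
        assert d.loc["b1", "b2"] < d.loc["a2", "b2"]

    def test_cophenetic_distances_invariant_to_input_order(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.random((5, 8)), index=list("abcde"))
        t1 = rscu_cluster(m)
        t2 = rscu_cluster(m.loc[list("daceb")])
        d1 = t1.cophenetic_distances().loc[list("abcde"), list("abcde")]
        d2 = t2.cophenetic_distances().loc[list("abcde"), list("abcde")]
        assert np.allclose(d1.values, d2.values)

    def test_newick_is_parseable_with_all_leaves(self):
        rng = np.random.default_rng(8)
        labels = [f"sp{i}" for i in range(6)]
        tree = rscu_cluster(pd.DataFrame(rng.random((6, 10)), index=labels))
        parsed = Phylo.read(io.StringIO(tree.newick), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(labels)

    def test_unknown_metric_rejected(self):
        with pytest.raises(Exception):
            rscu_cluster(self._matrix([[1, 2], [2, 1]], ["a", "b"]), metric="nope")
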
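import subprocess

import numpy as np
import pytest
from scipy import stats

from paracnv import (
    CountMatrix,
    GeneInterval,
    SampleMeta,
    bh_fdr,
    consensus_gcnvs,
    equalize_library_sizes,
    estimate_common_dispersion,
    exact_test_batch,
    nb_exact_test,
)


class TestNbExactTest:
    def test_balanced_equal_split_gives_one(self):
        assert nb_exact_test(25, 25, 10, 10, 0.1) == 1.0

    def test_poisson_limit_extreme_split(self):
        # phi=0, equal groups: conditional binomial; split (10, 0) gives
        # 2 * 0.5**10 (both extreme splits are the rejection region)
        p = nb_exact_test(10, 0, 10, 10, 0.0)
        assert p == pytest.approx(2 * 0.5**10, abs=1e-12)

    def test_symmetry_under_group_swap(self):
        for phi in (0.0, 0.2):
            assert nb_exact_test(30, 7, 8, 8, phi) == pytest.approx(
                nb_exact_test(7, 30, 8, 8, phi), abs=1e-12
            )

    def test_matches_binomial_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            a, b = (int(x) for x in rng.integers(0, 51, 2))
            if a + b == 0:
                continue
            ours = nb_exact_test(a, b, 10, 10, 0.0)
            oracle = stats.binomtest(a, a + b, 0.5).pvalue
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_unbalanced_groups_match_nb_product_enumeration(self):
        # independent oracle: P(a | N) from the product of the two group-sum
        # NB pmfs at an arbitrary common mean, enumerated over all splits
        phi, n_a, n_b = 0.2, 4, 7
        r_a, r_b = n_a / phi, n_b / phi
        rng = np.random.default_rng(11)
        for _ in range(10):
            a, b = (int(x) for x in rng.integers(0, 120, 2))
            N = a + b
            if N == 0:
                continue
            mu = 3.7  # arbitrary: the conditional law does not depend on it
            q = 1.0 / (1.0 + phi * mu)
            k = np.arange(N + 1)
            joint = stats.nbinom.pmf(k, r_a, q) * stats.nbinom.pmf(N - k, r_b, q)
            cond = joint / joint.sum()
            oracle = cond[cond <= cond[a] * (1 + 1e-7)].sum()
            assert nb_exact_test(a, b, n_a, n_b, phi) == pytest.approx(
                oracle, rel=1e-9
            )

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(1, 2, 3, 3, -0.1)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = (int(x) for x in rng.integers(0, 500, 2))
            p = nb_exact_test(a, b, 10, 10, float(rng.uniform(0, 2)))
            assert 0 < p <= 1


class TestExactTestBatch:
    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.1, 0.5])
    def test_matches_scalar_path(self, phi):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3000, 40)
        b = rng.integers(0, 3000, 40)
        batch = exact_test_batch(a, b, 10, 10, phi)
        scalar = np.array(
            [nb_exact_test(x, y, 10, 10, phi) for x, y in zip(a, b)]
        )
        np.testing.assert_allclose(batch, scalar, atol=1e-9)

    def test_screening_preserves_small_p_values(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3000, 200)
        b = rng.integers(0, 3000, 200)
        full = exact_test_batch(a, b, 10, 10, 0.1)
        screened = exact_test_batch(a, b, 10, 10, 0.1, screen_alpha=0.05)
        # exact wherever it matters; never pulls a >alpha gene under alpha
        small = full <= 0.05
        np.testing.assert_allclose(screened[small], full[small], atol=1e-9)
        assert (screened[~small] > 0.05).all()

    def test_matches_edger_exact_test(self, tmp_path):
        """Independent oracle: edgeR's exactTest at a fixed dispersion with
        equal library sizes (so neither side rescales counts)."""
        rng = np.random.default_rng(5)
        G, n, phi = 40, 6, 0.15
        mu = rng.uniform(20, 400, G)
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), (G, 2 * n))
        counts_path = tmp_path / "counts.tsv"
        np.savetxt(counts_path, counts, fmt="%d", delimiter="\t")
        out_path = tmp_path / "edger_p.tsv"
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'x <- as.matrix(read.table("{counts_path}"))\n'
            f'group <- factor(c(rep("A",{n}), rep("B",{n})))\n'
            f'd <- DGEList(counts=x, group=group, lib.size=rep(1e6, {2*n}))\n'
            f'res <- exactTest(d, dispersion={phi})\n'
            f'write.table(res$table$PValue, "{out_path}", '
            'row.names=FALSE, col.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        p_oracle = np.loadtxt(out_path)
        p_ours = exact_test_batch(
            counts[:, :n].sum(1), counts[:, n:].sum(1), n, n, phi
        )
        np.testing.assert_allclose(p_ours, p_oracle, rtol=0.01, atol=1e-4)


def _matrix_from_counts(counts, totals=None, n_a=None):
    counts = np.asarray(counts)
    G, S = counts.shape
    n_a = n_a if n_a is not None else S // 2
    genes = [GeneInterval(f"g{i}", "c", i * 1000, i * 1000 + 500) for i in range(G)]
    totals = totals if totals is not None else [1_000_000] * S
    samples = [
        SampleMeta(f"s{j}", "A" if j < n_a else "B", int(t))
        for j, t in enumerate(totals)
    ]
    return CountMatrix(genes, samples, counts)


class TestDispersion:
    def _simulate(self, phi, n_genes=2000, seed=0):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(30, 300, n_genes)[:, None] * np.ones(20)
        if phi == 0:
            counts = rng.poisson(mu)
        else:
            r = 1 / phi
            counts = rng.negative_binomial(r, r / (r + mu))
        return _matrix_from_counts(counts)

    def test_poisson_data_gives_near_zero(self):
        est = estimate_common_dispersion(self._simulate(0.0))
        assert est.phi < 0.05

    def test_recovers_known_dispersion(self):
        est = estimate_common_dispersion(self._simulate(0.1, seed=1))
        assert 0.05 <= est.phi <= 0.2

    def test_identical_counts_give_zero(self):
        m = _matrix_from_counts(np.full((1, 8), 50))
        assert estimate_common_dispersion(m).phi == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_common_dispersion(_matrix_from_counts(np.zeros((5, 6), int)))

    def test_equalization_scales_to_geometric_mean(self):
        counts = np.array([[100, 200], [10, 20]])
        pseudo, common = equalize_library_sizes(counts, np.array([1000, 4000]))
        assert common == pytest.approx(2000.0)
        np.testing.assert_array_equal(pseudo, [[200, 100], [20, 10]])


class TestBhFdr:
    def test_step_up_hand_computed(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_constant_vectors(self):
        assert bh_fdr([0.3]).tolist() == [0.3]
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(12)
        for _ in range(1000):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            ours = bh_fdr(p)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestConsensus:
    def _result(self, fdrs, mean_a=2.0, mean_b=1.0):
        import pandas as pd

        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(fdrs))],
                "mean_norm_A": mean_a if np.ndim(mean_a) else [mean_a] * len(fdrs),
                "mean_norm_B": mean_b if np.ndim(mean_b) else [mean_b] * len(fdrs),
                "p": fdrs,
                "fdr": fdrs,
            }
        )

    def test_significant_in_all_three_is_consensus(self):
        res = {k: self._result([0.01, 0.2]) for k in ("e70", "e100", "e130")}
        out = consensus_gcnvs(res)
        assert out.consensus_gcnv.tolist() == [True, False]
        assert out.direction.tolist()[0] == "increased_in_A"

    def test_two_of_three_is_not_consensus(self):
        res = {
            "e70": self._result([0.01]),
            "e100": self._result([0.01]),
            "e130": self._result([0.2]),
        }
        assert consensus_gcnvs(res).consensus_gcnv.tolist() == [False]

    def test_no_significant_genes_gives_empty_consensus(self):
        res = {k: self._result([0.9, 0.8]) for k in ("e70", "e100")}
        assert not consensus_gcnvs(res).consensus_gcnv.any()

    def test_direction_disagreement_dropped(self, caplog):
        res = {
            "e70": self._result([0.01], mean_a=2.0, mean_b=1.0),
            "e100": self._result([0.01], mean_a=1.0, mean_b=2.0),
        }
        import logging

        with caplog.at_level(logging.WARNING, logger="paracnv.detect"):
            out = consensus_gcnvs(res)
        assert not out.consensus_gcnv[0]
        assert "direction" in caplog.text

    def test_universe_is_intersection_of_filtered_sets(self):
        res = {
            "e70": self._result([0.01, 0.01]),
            "e100": self._result([0.01]),  # second gene filtered out here
        }
        out = consensus_gcnvs(res)
        assert out.gene_id.tolist() == ["g0"]

    def test_empty_universe_rejected(self):
        res = {
            "e70": self._result([0.01]),
            "e100": self._result([0.01]).assign(gene_id=["other"]),
        }
        with pytest.raises(ValueError, match="universe"):
            consensus_gcnvs(res)


class TestNullCalibration:
    def test_p_values_approximately_uniform_under_null(self):
        """NB data with no group effect: exact-test p-values are ~U(0,1)."""
        rng = np.random.default_rng(42)
        G, phi = 1500, 0.1
        mu = rng.uniform(50, 500, G)[:, None] * np.ones(20)
        r = 1 / phi
        counts = rng.negative_binomial(r, r / (r + mu))
        m = _matrix_from_counts(counts)
        est = estimate_common_dispersion(m)
        pseudo, _ = equalize_library_sizes(m.counts, m.totals)
        p = exact_test_batch(
            pseudo[:, :10].sum(1), pseudo[:, 10:].sum(1), 10, 10, est.phi
        )
        assert stats.kstest(p, "uniform").statistic < 0.05
        frac_sig = (bh_fdr(p) < 0.05).mean()
        assert frac_sig <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / G)
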
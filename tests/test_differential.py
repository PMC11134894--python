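"""Size factors, offsets, dispersion, NB GLM fitting and Wald testing."""

import numpy as np
import pandas as pd
import pytest

from eprint_tools.core import (CountTable, GeneExpressionTable, SampleInfo)
from eprint_tools.differential import (DifferentialBindingModel, build_design,
                                       build_offsets, deg_on_input,
                                       estimate_dispersion,
                                       estimate_size_factors, fit_nb_glm,
                                       match_input_samples, wald_and_adjust)
from eprint_tools.simulate import SimConfig, nb_draw, simulate_bundle


def make_samples(n_per_cond=2, assay="eprint", batches=None):
    out = []
    for ci, cond in enumerate(["ctrl", "kd"]):
        for r in range(n_per_cond):
            batch = batches[ci * n_per_cond + r] if batches else "b1"
            out.append(SampleInfo(f"{assay}_{cond}_{r}", assay, cond, batch))
    return out


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        counts = np.tile(np.array([[10], [50], [200]]), (1, 4))
        np.testing.assert_allclose(estimate_size_factors(counts), 1.0)

    def test_doubled_column(self):
        rng = np.random.default_rng(0)
        base = rng.integers(10, 500, size=(200, 1))
        counts = np.hstack([base, base, 2 * base])
        f = estimate_size_factors(counts)
        assert f[2] / f[0] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_single_sample(self):
        assert estimate_size_factors(np.array([[5], [10]])) == \
            pytest.approx([1.0])

    def test_fallback_on_no_common_nonzero(self):
        counts = np.array([[10, 0], [0, 20]])
        with pytest.warns(UserWarning, match="library-size"):
            f = estimate_size_factors(counts)
        assert f[1] / f[0] == pytest.approx(2.0)


class TestOffsets:
    def test_flat_host_reduces_to_size_factors(self):
        samples = make_samples(assay="input")
        expr = GeneExpressionTable(["g1"], samples,
                                   np.full((1, 4), 100))
        sf = np.array([1.0, 2.0, 0.5, 1.0])
        off = build_offsets(sf, expr, ["g1", "g1"], [0, 1, 2, 3])
        shifted = off - np.log(sf)[None, :]
        # column-constant shift per peak: all entries equal log(100)
        np.testing.assert_allclose(shifted, np.log(100.0))

    def test_pseudocount_floor(self):
        samples = make_samples(assay="input")
        expr = GeneExpressionTable(["g1"], samples,
                                   np.array([[0, 0, 100, 100]]))
        off = build_offsets(np.ones(4), expr, ["g1"], [0, 1, 2, 3])
        assert np.isfinite(off).all()
        assert off[0, 0] >= np.log(0.5) - 1e-9

    def test_missing_host_gene_is_an_error(self):
        samples = make_samples(assay="input")
        expr = GeneExpressionTable(["g1"], samples, np.full((1, 4), 10))
        with pytest.raises(ValueError, match="g2"):
            build_offsets(np.ones(4), expr, ["g1", "g2"], [0, 1, 2, 3])

    def test_input_matching_by_condition_and_replicate(self):
        ep = make_samples(assay="eprint")
        inp = make_samples(assay="input")
        assert match_input_samples(ep, inp) == [0, 1, 2, 3]
        with pytest.raises(ValueError):
            match_input_samples(ep, inp[:2])


class TestDispersion:
    def test_poisson_counts_give_near_zero(self):
        rng = np.random.default_rng(3)
        mu = rng.uniform(50, 500, size=1000)
        counts = rng.poisson(np.tile(mu[:, None], (1, 8)))
        X = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        off = np.zeros((1000, 8))
        alpha = estimate_dispersion(counts, X, off)
        assert np.median(alpha) < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(4)
        mu = rng.uniform(100, 400, size=500)
        counts = np.stack([nb_draw(rng, np.full(8, m), 0.2) for m in mu])
        X = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        alpha = estimate_dispersion(counts, X, np.zeros((500, 8)))
        assert 0.1 <= np.median(alpha) <= 0.4

    def test_constant_counts_hit_lower_clamp(self):
        counts = np.full((1, 8), 100)
        X = np.column_stack([np.ones(8), np.repeat([0, 1], 4)])
        alpha = estimate_dispersion(
            np.vstack([counts, counts + np.arange(8)]), X, np.zeros((2, 8)))
        assert alpha[0] <= 1e-6


class TestNbGlm:
    def test_poisson_limit_closed_form(self):
        # counts exactly mu and 2mu -> condition coefficient log 2
        y = np.array([100.0, 100.0, 200.0, 200.0])
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        beta, cov, conv = fit_nb_glm(y, X, np.zeros(4), 1e-10)
        assert conv
        assert beta[1] == pytest.approx(np.log(2.0), abs=1e-6)
        assert beta[0] == pytest.approx(np.log(100.0), abs=1e-6)

    def test_reference_only_condition_zero_coefficient(self):
        y = np.array([100.0, 90.0, 110.0, 100.0])
        X = np.column_stack([np.ones(4), np.zeros(4)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_nb_glm(y, X, np.zeros(4), 0.1)  # all-reference: rank deficient

    def test_confounded_batch_is_rank_error(self):
        samples = make_samples(batches=["b1", "b1", "b2", "b2"])
        with pytest.raises(ValueError, match="rank"):
            build_design(samples)

    def test_balanced_batch_design_ok(self):
        samples = make_samples(batches=["b1", "b2", "b1", "b2"])
        X, names, alt = build_design(samples)
        assert X.shape == (4, 3)
        assert alt == "kd"


class TestWaldAdjust:
    def test_bh_worked_example(self):
        # BH on (0.01, 0.02, 0.03, 0.04): padj_i = p_i * 4 / i = 0.04 for all
        frame = pd.DataFrame({
            "peak_id": list("abcd"),
            "log2FC": [3.0, 2.5, 2.0, 1.5],
            "se": np.array([3.0, 2.5, 2.0, 1.5])
                  / np.array([2.5758, 2.3263, 2.1701, 2.0537]),
        })
        out = wald_and_adjust(frame)
        np.testing.assert_allclose(out["p"], [0.01, 0.02, 0.03, 0.04],
                                   atol=1e-4)
        np.testing.assert_allclose(out["padj"], 0.04, atol=1e-4)

    def test_single_peak_padj_equals_p(self):
        frame = pd.DataFrame({"peak_id": ["a"], "log2FC": [1.0], "se": [0.5]})
        out = wald_and_adjust(frame)
        assert out["padj"].iloc[0] == pytest.approx(out["p"].iloc[0])


class TestModel:
    def test_effect_recovery_planted_lfc(self):
        cfg = SimConfig(seed=11, n_genes=150, peaks_per_gene=(4, 4),
                        with_sequence=False, frac_diff_peaks=0.25,
                        diff_log2fc=1.0, mean_peak_count=100.0,
                        dispersion=0.1, exon_length=(150, 250),
                        intron_length=(200, 300))
        b = simulate_bundle(cfg)
        res = DifferentialBindingModel(b.counts).fit()
        planted = {p: f for p, f in b.truth.true_lfc.items() if f != 0}
        est = np.array([res.frame.loc[p, "log2FC"] * np.sign(f)
                        for p, f in planted.items()])
        assert abs(est.mean() - 1.0) < 0.1

    def test_ranking_is_strict_total_order(self):
        cfg = SimConfig(seed=5, n_genes=30, with_sequence=False)
        b = simulate_bundle(cfg)
        res = DifferentialBindingModel(b.counts, b.gene_expr,
                                       b.truth.peak_hosts).fit()
        ranked = res.ranked()
        keys = list(zip(ranked["wald"], ranked["peak_id"]))
        assert len(keys) == len(set(keys))
        assert keys == sorted(keys, key=lambda t: (-t[0], t[1]))

    def test_padj_at_least_p(self):
        cfg = SimConfig(seed=6, n_genes=30, with_sequence=False)
        b = simulate_bundle(cfg)
        f = DifferentialBindingModel(b.counts).fit().frame.dropna(
            subset=["p"])
        assert (f["padj"] >= f["p"] - 1e-12).all()

    def test_summary_mentions_offsets(self):
        cfg = SimConfig(seed=6, n_genes=30, with_sequence=False)
        b = simulate_bundle(cfg)
        res = DifferentialBindingModel(b.counts, b.gene_expr,
                                       b.truth.peak_hosts).fit()
        assert "host-gene offsets:  yes" in res.summary()


class TestDegOnInput:
    def test_planted_twofold_genes_recovered(self):
        # 2v2 with two batches; planted 2x genes at mean 200
        rng = np.random.default_rng(21)
        n_genes, n_de = 400, 80
        samples = [SampleInfo(f"in_{c}_{r}", "input", c, f"b{r % 2 + 1}")
                   for c in ("ctrl", "kd") for r in range(4)]
        mu = np.full(n_genes, 200.0)
        de = np.zeros(n_genes, dtype=bool)
        de[:n_de] = True
        counts = np.zeros((n_genes, 8), dtype=np.int64)
        for j, s in enumerate(samples):
            m = mu * np.where(de & (s.condition == "kd"), 2.0, 1.0)
            counts[:, j] = nb_draw(rng, m, 0.05)
        expr = GeneExpressionTable([f"g{i}" for i in range(n_genes)],
                                   samples, counts)
        res = deg_on_input(expr)
        frame = res.frame
        power = (frame["padj"].iloc[de.nonzero()[0]] < 0.05).mean()
        assert power >= 0.8

    def test_null_genes_near_nominal_type_i(self):
        rng = np.random.default_rng(22)
        n_genes = 400
        samples = [SampleInfo(f"in_{c}_{r}", "input", c)
                   for c in ("ctrl", "kd") for r in range(2)]
        counts = np.stack([nb_draw(rng, np.full(4, m), 0.05)
                           for m in rng.uniform(100, 400, n_genes)])
        expr = GeneExpressionTable([f"g{i}" for i in range(n_genes)],
                                   samples, counts)
        frame = deg_on_input(expr).frame
        fpr = (frame["p"] < 0.05).mean()
        assert 0.02 < fpr < 0.09

    def test_zero_count_gene_flagged(self):
        samples = [SampleInfo(f"in_{c}_{r}", "input", c)
                   for c in ("ctrl", "kd") for r in range(2)]
        counts = np.array([[100, 110, 90, 105], [0, 0, 0, 0]])
        expr = GeneExpressionTable(["g1", "gzero"], samples, counts)
        frame = deg_on_input(expr).frame
        assert not frame.loc["gzero", "converged"]
        assert np.isnan(frame.loc["gzero", "p"])
        assert frame.loc["g1", "converged"]
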
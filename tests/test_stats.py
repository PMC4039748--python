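"""Efficiency statistics: condition means, moderated t, prior fit, BH."""

from __future__ import annotations

import math
import shutil
import subprocess

import numpy as np
import pytest
from scipy import special, stats as sps

import polyeff as pe
from polyeff.stats import TL_CONTRAST_SCALE_NUM, bh_adjust

from conftest import make_dataset


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Quadratic-time application of the step-up definition."""
    n = len(p)
    out = np.empty(n)
    for i, pi in enumerate(p):
        rank_i = np.sum(p <= pi)  # maximal rank among ties
        candidates = []
        for j, pj in enumerate(p):
            rank_j = np.sum(p <= pj)
            if rank_j >= rank_i:
                candidates.append(pj * n / rank_j)
        out[i] = min(1.0, min(candidates))
    return out


class TestConditionMeans:
    def test_constant_replicates_give_zero_variance(self):
        values = np.array([[1, 1, 2, 2, 0, 0, 0, 0]], dtype=float)
        data = make_dataset(values)
        m = pe.condition_means(data)
        assert (m.p0[0], m.p6[0], m.np0[0], m.np6[0]) == (1, 2, 0, 0)
        assert m.s_sq[0] == 0
        assert m.df == 4

    def test_global_shift_moves_means_not_variance(self, small_dataset):
        data, _ = small_dataset
        shifted = data.copy()
        shifted.values = shifted.values + 3.25
        m0, m1 = pe.condition_means(data), pe.condition_means(shifted)
        for cell in ("p0", "p6", "np0", "np6"):
            np.testing.assert_allclose(
                getattr(m1, cell), getattr(m0, cell) + 3.25, atol=1e-12
            )
        np.testing.assert_allclose(m1.s_sq, m0.s_sq, atol=1e-12)

    def test_pooled_variance_equals_direct_sse(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(50, 12))
        data = make_dataset(values)
        m = pe.condition_means(data)
        sse = np.zeros(50)
        for block in (values[:, :3], values[:, 3:6], values[:, 6:9], values[:, 9:]):
            sse += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        np.testing.assert_allclose(m.s_sq, sse / 8, rtol=1e-12)

    def test_single_replicate_cell_is_rejected(self):
        values = np.random.default_rng(0).normal(size=(3, 4))
        with pytest.raises(pe.FormatError):
            pe.condition_means(make_dataset(values, r=1))


class TestEfficiencies:
    @pytest.mark.parametrize(
        "cells, expected_tc, expected_tl",
        [((1, 2, 0, 1), 1.0, 0.0), ((0, 2, 0, 1), 1.5, 1.0)],
    )
    def test_worked_examples(self, cells, expected_tc, expected_tl):
        p0, p6, np0, np6 = cells
        values = np.repeat([[p0, p6, np0, np6]], 2, axis=1).astype(float)
        m = pe.condition_means(make_dataset(values.reshape(1, 8)))
        tc, tl = pe.efficiencies(m)
        assert tc[0] == pytest.approx(expected_tc, abs=1e-12)
        assert tl[0] == pytest.approx(expected_tl, abs=1e-12)

    def test_fraction_change_reconstruction_identity(self, small_dataset):
        data, _ = small_dataset
        m = pe.condition_means(data)
        tc, tl = pe.efficiencies(m)
        np.testing.assert_allclose(m.p6 - m.p0, tc + tl / 2, atol=1e-12)
        np.testing.assert_allclose(m.np6 - m.np0, tc - tl / 2, atol=1e-12)


class TestEstimatePrior:
    def test_identical_variances_give_infinite_d0(self):
        prior = pe.estimate_prior(np.full(100, 0.04), 8)
        assert math.isinf(prior.d0)
        # fixed point of the moment transform, not exactly the common value
        e = math.log(0.04) - special.digamma(4) + math.log(4)
        assert prior.s0_sq == pytest.approx(math.exp(e))

    def test_all_zero_variances_error(self):
        with pytest.raises(ValueError, match="zero"):
            pe.estimate_prior(np.zeros(10), 8)

    @pytest.mark.parametrize(
        "d0, s0, rel_d0", [(4.0, 0.05, 0.25), (1.0, 0.05, 0.30)]
    )
    def test_simulation_recovery(self, d0, s0, rel_d0):
        rng = np.random.default_rng(77)
        n, dg = 10000, 8
        sigma_sq = s0 * d0 / rng.chisquare(d0, n)
        s_sq = sigma_sq * rng.chisquare(dg, n) / dg
        prior = pe.estimate_prior(s_sq, dg)
        assert prior.d0 == pytest.approx(d0, rel=rel_d0)
        assert prior.s0_sq == pytest.approx(s0, rel=0.10)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_agrees_with_limma_fitFDist(self, tmp_path):
        """Independent oracle: limma's moment fit of the variance prior."""
        rng = np.random.default_rng(42)
        d0, s0, dg, n = 4.0, 0.05, 8, 2000
        s_sq = s0 * d0 / rng.chisquare(d0, n) * rng.chisquare(dg, n) / dg
        np.savetxt(tmp_path / "svar.txt", s_sq)
        out = subprocess.run(
            [
                "Rscript", "-e",
                f'x <- scan("{tmp_path}/svar.txt"); '
                "f <- limma::fitFDist(x, df1=8); cat(f$df2, f$scale)",
            ],
            capture_output=True, text=True, timeout=120, check=True,
        )
        r_d0, r_s0 = map(float, out.stdout.split())
        prior = pe.estimate_prior(s_sq, dg)
        assert prior.d0 == pytest.approx(r_d0, rel=1e-4)
        assert prior.s0_sq == pytest.approx(r_s0, rel=1e-4)


class TestModeratedT:
    def test_zero_effect_gives_t0_p1(self):
        prior = pe.ModerationPrior(d0=4, s0_sq=0.05)
        t, p, _ = pe.moderated_t(0.0, 0.04, 8, prior, 4 / 3)
        assert t == 0 and p == 1

    def test_hand_computed_formula_chain(self):
        """effect 1.2, s2 0.04, dg 8, d0 4, s0 0.05, scale 4/3."""
        s_post = (4 * 0.05 + 8 * 0.04) / (4 + 8)
        expected_t = 1.2 / math.sqrt(s_post * 4 / 3)
        expected_p = 2 * sps.t.sf(abs(expected_t), df=12)
        prior = pe.ModerationPrior(d0=4, s0_sq=0.05)
        t, p, df = pe.moderated_t(1.2, 0.04, 8, prior, 4 / 3)
        assert float(t) == pytest.approx(expected_t, rel=1e-12)
        assert float(p) == pytest.approx(expected_p, rel=1e-12)
        assert df == 12

    def test_no_moderation_limit_is_ordinary_t(self):
        """d0 -> 0 recovers the ordinary t-statistic on d_g df."""
        prior = pe.ModerationPrior(d0=1e-12, s0_sq=0.05)
        t, _, df = pe.moderated_t(0.8, 0.09, 8, prior, 4 / 3)
        ordinary = 0.8 / math.sqrt(0.09 * 4 / 3)
        assert float(t) == pytest.approx(ordinary, rel=1e-9)
        assert df == pytest.approx(8, abs=1e-9)

    def test_infinite_d0_is_z_statistic_with_prior_variance(self):
        prior = pe.ModerationPrior(d0=np.inf, s0_sq=0.05)
        t, p, df = pe.moderated_t(1.0, 0.5, 8, prior, 4 / 3)
        z = 1.0 / math.sqrt(0.05 * 4 / 3)
        assert float(t) == pytest.approx(z, rel=1e-12)
        assert float(p) == pytest.approx(2 * sps.norm.sf(z), rel=1e-12)
        assert math.isinf(df)

    def test_zero_posterior_variance_flags_p0(self):
        prior = pe.ModerationPrior(d0=1e-300, s0_sq=1e-300)
        with pytest.warns(RuntimeWarning):
            _, p, _ = pe.moderated_t(1.0, 0.0, 8, prior, 4 / 3)
        assert float(p) == 0.0


class TestBhAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_three_p_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_quadratic_oracle_and_preserves_ranking(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            p = rng.random(200)
            fdr = bh_adjust(p)
            np.testing.assert_allclose(fdr, bh_oracle(p), atol=1e-12)
            assert np.all(fdr >= p - 1e-15)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(fdr[order]) >= -1e-15)


def test_null_simulation_false_discovery_fraction():
    """Global null: fraction of genes with fdr_TL < 0.05 stays below 0.07."""
    props = np.zeros(9)
    props[8] = 1.0
    rates = []
    for seed in range(20):
        cfg = pe.SimulationConfig(
            n_genes=2000, n_spikeins=20, group_proportions=props, seed=1000 + seed
        )
        data, _ = pe.simulate_expression(cfg)
        normalized, _ = pe.normalize_spikein(data)
        records = pe.analyze(normalized)
        rates.append((records["fdr_TL"] < 0.05).mean())
    assert np.mean(rates) <= 0.07


def test_analyze_excludes_spikeins_and_reports_all_columns(small_dataset):
    data, _ = small_dataset
    records = pe.analyze(data)
    assert len(records) == (~data.spikein).sum()
    assert list(records.columns) == [
        "gene_id", "TC", "TL", "t_TC", "t_TL", "p_TC", "p_TL", "fdr_TC", "fdr_TL",
    ]
    assert np.all((records["fdr_TC"] >= records["p_TC"] - 1e-15))
    assert records[["p_TC", "p_TL"]].to_numpy().min() >= 0
    assert records[["p_TC", "p_TL"]].to_numpy().max() <= 1
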
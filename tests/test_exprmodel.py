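"""Expression transforms, stratified GC4 regression, bootstrap ellipses,
and decay-curve fitting."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from gcsplice.exprmodel import (
    bootstrap_ellipse,
    export_fraction,
    fit_decay,
    prepare_expression,
    regress_gc4,
)
from gcsplice.sortquant import BinCountMatrix, rcc
from gcsplice.synthgen import SimulationConfig, simulate_expression


def planted_table(n, b_u, b_s, noise, seed, unspliced_frac=0.5):
    cfg = SimulationConfig(seed=seed)
    cfg.expression.n_transcripts = n
    cfg.expression.b_unspliced = b_u
    cfg.expression.b_spliced = b_s
    cfg.expression.noise_sd = noise
    cfg.expression.unspliced_fraction = unspliced_frac
    table, truth = simulate_expression(cfg)
    return table, truth


class TestPrepareExpression:
    def test_pseudocount_log_transform(self):
        df = pd.DataFrame({"measure": [1.0]})
        out = prepare_expression(df)
        assert out["measure"].iloc[0] == pytest.approx(math.log2(1.0001))

    def test_raw_zeros_removed_before_pseudocount(self):
        df = pd.DataFrame({"measure": [0.0, 2.0, 0.0, 4.0]})
        out = prepare_expression(df)
        assert len(out) == 2
        assert out["measure"].tolist() == pytest.approx(
            [math.log2(2.0001), math.log2(4.0001)]
        )

    def test_zero_pseudocount_is_plain_log2(self):
        df = pd.DataFrame({"measure": [8.0]})
        out = prepare_expression(df, pseudocount=0.0)
        assert out["measure"].iloc[0] == pytest.approx(3.0)

    def test_export_fractions_not_transformed(self):
        df = pd.DataFrame({"measure": [0.4, 0.0]})
        out = prepare_expression(df, log_transform=False)
        assert out["measure"].tolist() == [0.4, 0.0]

    def test_negative_measure_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            prepare_expression(pd.DataFrame({"measure": [-1.0]}))

    def test_monotone_in_raw_measure(self, rng):
        raw = np.sort(rng.uniform(0.01, 100, size=50))
        out = prepare_expression(pd.DataFrame({"measure": raw}))
        assert (np.diff(out["measure"]) > 0).all()

    def test_spliced_flag_derived_from_exon_count(self):
        df = pd.DataFrame({"measure": [1, 1, 1], "exon_count": [1, 2, 9]})
        out = prepare_expression(df)
        assert out["spliced"].tolist() == [False, True, True]


class TestExportFraction:
    @pytest.mark.parametrize("nuc,cyto,expected", [(1, 1, 0.5), (0, 5, 0.0), (3, 1, 0.75)])
    def test_examples(self, nuc, cyto, expected):
        assert export_fraction(nuc, cyto) == pytest.approx(expected)

    def test_both_zero_flagged(self):
        assert np.isnan(export_fraction(np.array([0.0]), np.array([0.0]))[0])

    def test_complement_of_rcc(self, rng):
        counts = rng.integers(100, 10_000, size=(10, 2)).astype(float)
        m = BinCountMatrix(
            counts=pd.DataFrame(counts, columns=["cyto", "nuc"],
                                index=pd.Index([f"v{i}" for i in range(10)], name="variant_id"))
        )
        score = rcc(m, min_reads=0)["score"].to_numpy()
        frac = export_fraction(counts[:, 1], counts[:, 0])
        assert np.allclose(frac, 1.0 - score)


class TestRegressGC4:
    def test_noiseless_slope_recovered_exactly(self):
        table, _ = planted_table(200, b_u=4.0, b_s=0.0, noise=0.0, seed=1)
        prepared = prepare_expression(table, pseudocount=0.0)
        fit_u = regress_gc4(prepared, "unspliced")
        fit_s = regress_gc4(prepared, "spliced")
        assert fit_u.coefficient == pytest.approx(4.0, abs=1e-9)
        assert fit_s.coefficient == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_data_same_slope_smaller_stderr(self):
        table, _ = planted_table(300, b_u=2.0, b_s=1.0, noise=0.5, seed=2)
        prepared = prepare_expression(table, pseudocount=0.0)
        doubled = pd.concat([prepared, prepared], ignore_index=True)
        one, two = regress_gc4(prepared, "spliced"), regress_gc4(doubled, "spliced")
        assert two.coefficient == pytest.approx(one.coefficient)
        assert two.stderr < one.stderr

    def test_recovery_within_three_stderr(self):
        table, _ = planted_table(2000, b_u=4.0, b_s=0.0, noise=1.0, seed=3)
        prepared = prepare_expression(table, pseudocount=0.0)
        fit = regress_gc4(prepared, "unspliced")
        assert abs(fit.coefficient - 4.0) < 3 * fit.stderr

    def test_constant_gc4_rejected(self):
        df = pd.DataFrame({"measure": [1.0, 2.0, 3.0], "exon_count": [1, 1, 1], "gc4": [0.5] * 3})
        with pytest.raises(ValueError, match="constant GC4"):
            regress_gc4(df, "unspliced")

    def test_small_stratum_rejected(self):
        df = pd.DataFrame({"measure": [1.0, 2.0], "exon_count": [1, 1], "gc4": [0.4, 0.6]})
        with pytest.raises(ValueError, match=">=3"):
            regress_gc4(df, "unspliced")


class TestBootstrapEllipse:
    def test_bit_reproducible_given_seed(self):
        table, _ = planted_table(400, 4.0, 0.0, 1.0, seed=4)
        prepared = prepare_expression(table, pseudocount=0.0)
        a = bootstrap_ellipse(prepared, n_boot=200, seed=9)
        b = bootstrap_ellipse(prepared, n_boot=200, seed=9)
        assert np.array_equal(a.coeffs, b.coeffs)
        assert a.radius == b.radius

    def test_zero_noise_gives_degenerate_ellipse(self):
        table, _ = planted_table(200, 4.0, 0.0, 0.0, seed=5)
        prepared = prepare_expression(table, pseudocount=0.0)
        res = bootstrap_ellipse(prepared, n_boot=100, seed=0)
        assert np.allclose(res.coeffs.std(axis=0), 0.0, atol=1e-8)
        # ellipse collapses to (numerically) a point around the exact fit
        assert res.radius < 1e-3
        assert res.contains((4.0, 0.0))

    def test_center_near_planted_pair(self):
        table, _ = planted_table(2000, 4.0, 0.0, 1.0, seed=6)
        prepared = prepare_expression(table, pseudocount=0.0)
        res = bootstrap_ellipse(prepared, n_boot=400, seed=1)
        boot_se = res.coeffs.std(axis=0)
        assert abs(res.center[0] - 4.0) < 3 * boot_se[0]
        assert abs(res.center[1] - 0.0) < 3 * boot_se[1]
        assert res.contains((4.0, 0.0))

    def test_ellipse_encloses_95pct_of_replicates(self):
        table, _ = planted_table(800, 3.0, 1.0, 1.0, seed=7)
        prepared = prepare_expression(table, pseudocount=0.0)
        res = bootstrap_ellipse(prepared, n_boot=500, seed=2)
        inside = np.mean([res.contains(c) for c in res.coeffs])
        assert inside >= 0.95

    def test_seed_invariance_of_ellipse_area(self):
        table, _ = planted_table(2000, 4.0, 0.0, 1.0, seed=8)
        prepared = prepare_expression(table, pseudocount=0.0)
        areas = []
        for seed in (1, 2):
            res = bootstrap_ellipse(prepared, n_boot=500, seed=seed)
            vals = np.linalg.eigvalsh(res.cov)
            areas.append(math.pi * res.radius**2 * math.sqrt(vals[0] * vals[1]))
        assert abs(areas[0] / areas[1] - 1.0) < 0.2


class TestFitDecay:
    def test_closed_form_half_life(self):
        t = np.array([0.0, 0.5, 1.0, 2.0, 3.0])
        fit = fit_decay(t, np.exp(-math.log(2) * t))
        assert fit.k == pytest.approx(-math.log(2))
        assert fit.t_half == pytest.approx(1.0)
        assert fit.decaying

    def test_constant_series_flagged_stable(self):
        fit = fit_decay([0, 1, 2, 4], [1.0, 1.0, 1.0, 1.0])
        assert fit.t_half == math.inf
        assert not fit.decaying

    def test_noisy_recovery(self, rng):
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
        ks = []
        for _ in range(50):
            levels = np.exp(-0.1 * t) * (1 + rng.normal(0, 0.05, len(t)))
            ks.append(-fit_decay(t, np.clip(levels, 1e-9, None)).k)
        assert abs(np.mean(ks) / 0.1 - 1) < 0.05

    def test_input_validation(self):
        with pytest.raises(ValueError, match=">=3"):
            fit_decay([0, 1], [1.0, 0.5])
        with pytest.raises(ValueError, match="positive"):
            fit_decay([0, 1, 2], [1.0, 0.0, 0.5])
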
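"""Banded loss, multi-modal objective, and the genetic algorithm."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from israpop.calibration import (GAConfig, MeasurementPoint, ObjectiveConfig,
                                 _ga_minimize, banded_loss, objective,
                                 fit_stage1_tf, simulate_tf_subsystem)
from israpop.params import default_params, stage1_names
from israpop.protocols import named_protocol


def _pt(mean=1.0, sd=0.1, **kw):
    base = dict(condition="combo", modality="protein_rel", species="bcl2",
                time_h=72.0, mean=mean, sd=sd)
    base.update(kw)
    return MeasurementPoint(**base)


class TestBandedLoss:
    def test_zero_inside_band(self):
        assert banded_loss(0.95, _pt()) == 0.0
        assert banded_loss(1.1, _pt()) == 0.0   # edge inclusive

    def test_branch_formulas(self):
        assert banded_loss(1.21, _pt()) == pytest.approx(0.1)        # (1.21-1.1)/1.1
        assert banded_loss(0.45, _pt()) == pytest.approx(0.5)        # (0.9-0.45)/0.9

    def test_band_multiplier_widens(self):
        assert banded_loss(1.15, _pt(), k=2.0) == 0.0
        assert banded_loss(1.15, _pt(), k=1.0) > 0.0

    def test_degenerate_band_floor(self):
        p = _pt(sd=0.0)
        assert banded_loss(1.0, p, min_band_rel=0.02) == 0.0
        assert banded_loss(1.019, p, min_band_rel=0.02) == 0.0
        assert banded_loss(1.2, p, min_band_rel=0.02) > 0.0

    def test_nonpositive_lower_edge_raises(self):
        with pytest.raises(ValueError):
            banded_loss(0.5, _pt(mean=0.1, sd=0.2))

    def test_nonnegative_and_weakly_increasing_outside(self):
        p = _pt()
        xs = np.linspace(1.1, 3.0, 50)
        losses = [banded_loss(x, p) for x in xs]
        assert all(l >= 0 for l in losses)
        assert np.all(np.diff(losses) >= 0)
        xs_lo = np.linspace(0.9, 0.05, 50)
        losses_lo = [banded_loss(x, p) for x in xs_lo]
        assert np.all(np.diff(losses_lo) >= 0)


class TestObjective:
    @pytest.fixture(scope="class")
    def tf_dataset(self, params):
        """Noise-free c-Myc/Chop rows generated from the TF subsystem."""
        from israpop.ratelaws import basal_tf_levels
        myc0, chop0 = basal_tf_levels(params)
        rows = []
        for cond in ("untreated", "ven_mono", "ted_mono", "combo"):
            # match the objective's default output grid so that scheduled
            # times snap to the same grid points
            traj = simulate_tf_subsystem(params, named_protocol(cond, output_points=400))
            for t in (24.0, 48.0, 72.0):
                rows.append((cond, "protein_rel", "myc", t,
                             traj.value_at(traj.state("myc"), t) / myc0, 0.0))
            for t in (24.0, 48.0, 72.0, 96.0):
                rows.append((cond, "protein_rel", "chop", t,
                             traj.value_at(traj.state("chop"), t) / chop0, 0.0))
        return pd.DataFrame(rows, columns=["condition", "modality", "species",
                                           "time_h", "mean", "sd"])

    def test_zero_at_truth(self, params, tf_dataset):
        out = objective(params, tf_dataset, tf_only=True)
        assert out["total"] == 0.0

    def test_row_permutation_invariant(self, params, tf_dataset):
        shuffled = tf_dataset.sample(frac=1.0, random_state=3)
        a = objective(params, tf_dataset, tf_only=True)
        b = objective(params, shuffled, tf_only=True)
        assert a["total"] == b["total"]

    def test_single_out_of_band_point(self, params, tf_dataset):
        ds = tf_dataset.copy()
        # push one chop point far out of its band: total = w_p * that loss
        i = ds[(ds.species == "chop") & (ds.condition == "combo")].index[0]
        true_val = ds.loc[i, "mean"]
        ds.loc[i, "mean"] = true_val * 2.0
        cfg = ObjectiveConfig(weights=(1.0, 0.1, 0.1))
        out = objective(params, ds, cfg, tf_only=True)
        point = MeasurementPoint("combo", "protein_rel", "chop",
                                 float(ds.loc[i, "time_h"]),
                                 float(ds.loc[i, "mean"]), 0.0)
        expected = banded_loss(true_val, point, min_band_rel=cfg.min_band_rel)
        assert out["total"] == pytest.approx(expected, rel=1e-3)
        assert out["f_v"] == 0.0 and out["f_c"] == 0.0

    def test_failure_penalty_is_finite_sentinel(self, tf_dataset):
        bad = default_params()
        bad["chop_deg"] = 0.0   # basal Chop level diverges -> invalid model
        out = objective(bad, tf_dataset, tf_only=True)
        assert out["total"] >= 1.0e6
        assert "failure" in out


class TestGA:
    BOWL = staticmethod(lambda x: float(np.sum((x - 0.3) ** 2)))

    def _bounds(self, ndim):
        soft = np.tile([-1.0, 1.0], (ndim, 1))
        hard = np.tile([-10.0, 10.0], (ndim, 1))
        return soft, hard

    def test_deterministic_for_fixed_seed(self):
        soft, hard = self._bounds(4)
        cfg = GAConfig(population_size=20, n_blocks=2, iterations_per_block=10,
                       seed=5)
        a = _ga_minimize(self.BOWL, soft, hard, cfg)
        b = _ga_minimize(self.BOWL, soft, hard, cfg)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_finds_quadratic_minimum(self):
        soft, hard = self._bounds(3)
        cfg = GAConfig(population_size=30, n_blocks=3, iterations_per_block=15,
                       seed=1, polish=True)
        x, f, *_ = _ga_minimize(self.BOWL, soft, hard, cfg)
        assert f < 1e-6
        assert np.allclose(x, 0.3, atol=1e-2)

    def test_boundary_adaptation_respects_limits(self):
        # minimum outside the soft box: adaptation must move the bounds,
        # each step bounded by the configured fraction, never past hard
        fun = lambda x: float(np.sum((x - 2.0) ** 2))
        soft = np.array([[-1.0, 1.0]])
        hard = np.array([[-1.5, 1.5]])
        cfg = GAConfig(population_size=16, n_blocks=6, iterations_per_block=6,
                       seed=2, stall_blocks=10)
        x, f, trace, blog, _ = _ga_minimize(fun, soft, hard, cfg)
        assert len(blog) > 0
        for entry in blog:
            assert abs(entry["shift"]) <= 0.10 * 2.0 + 1e-12
        assert x[0] <= 1.5 + 1e-12

    def test_late_phase_adjustments_are_small(self):
        # minimum far outside: boundary pressure persists into late blocks
        fun = lambda x: float(np.sum((x - 10.0) ** 2))
        soft = np.array([[-1.0, 1.0]])
        hard = np.array([[-50.0, 50.0]])
        cfg = GAConfig(population_size=16, n_blocks=9, iterations_per_block=6,
                       seed=3, stall_blocks=20)
        *_, blog, _ = _ga_minimize(fun, soft, hard, cfg)
        late = [e for e in blog if e["block"] >= 6]
        assert late, "expected boundary pressure in the late phase"
        for e in late:
            assert e["max_fraction"] == cfg.soft_adjust_late

    def test_seed_individual_dominance(self):
        """Elitism: the returned objective never exceeds the seed's."""
        soft, hard = self._bounds(5)
        x0 = np.full(5, 0.31)
        cfg = GAConfig(population_size=12, n_blocks=1, iterations_per_block=3,
                       seed=9)
        x, f, *_ = _ga_minimize(self.BOWL, soft, hard, cfg, x0=x0)
        assert f <= self.BOWL(x0)


class TestStage1:
    def test_stage1_recovers_tf_trajectories(self, params):
        """Displaced drug/TF parameters are refit on noise-free TF data to
        a mean trajectory error below 5%."""
        from israpop.ratelaws import basal_tf_levels
        from israpop.synthetic import generate
        truth = params
        ds = generate(truth, noise_cv={"protein_rel": 0.0, "viability": 0.0,
                                       "live_count": 0.0}, seed=4)
        free = ["chop_ted_amp", "chop_ted_K", "ted_k_uptake", "chop_syn_amp"]
        start = truth.copy()
        start.set_status(start.free_names, "fixed")
        start.set_status(free, "free")
        for i, name in enumerate(free):
            e = start.entry(name)
            e.value = float(np.clip(e.value * (1.3 if i % 2 else 0.7),
                                    e.soft_lo, e.soft_hi))
        ga = GAConfig(population_size=16, n_blocks=2, iterations_per_block=6,
                      seed=11, polish=True)
        fitted, report = fit_stage1_tf(start, ds.data, ga)
        assert report.stage == "stage1_tf"
        assert set(report.free_names) <= set(stage1_names(truth))

        myc0, chop0 = basal_tf_levels(fitted)
        tf_rows = ds.data[(ds.data.modality == "protein_rel")
                          & ds.data.species.isin(["myc", "chop"])]
        errs = []
        for cond, grp in tf_rows.groupby("condition"):
            traj = simulate_tf_subsystem(fitted, named_protocol(cond, output_points=300))
            for _, r in grp.iterrows():
                ref = myc0 if r["species"] == "myc" else chop0
                sim = traj.value_at(traj.state(r["species"]), r["time_h"]) / ref
                errs.append(abs(sim - r["mean"]) / r["mean"])
        assert np.mean(errs) < 0.05

    def test_stage1_rejects_downstream_parameters(self, params):
        ds = pd.DataFrame([["combo", "protein_rel", "chop", 24.0, 2.0, 0.2]],
                          columns=["condition", "modality", "species",
                                   "time_h", "mean", "sd"])
        with pytest.raises(ValueError):
            fit_stage1_tf(params.copy(), ds, GAConfig(population_size=4,
                                                      n_blocks=1,
                                                      iterations_per_block=1),
                          free_names=["mcl1_deg"])
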
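"""Synthetic curve generator: closed-form ground truth and determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tacall
from tacall import SimConfig, TacallError


def noiseless_config(**kw):
    base = dict(noise_sd=0.0, rox_sd=0.0, hook_probability=0.0,
                drift_range=(0.0, 0.0))
    base.update(kw)
    return SimConfig(**base)


class TestClosedFormCt:
    def test_midpoint_at_half_crossing(self):
        for k in (0.4, 1.0, 1.2):
            assert tacall.closed_form_ct(25, k, 0.5) == pytest.approx(25.0)

    def test_worked_value(self):
        assert tacall.closed_form_ct(25, 1, 0.05) == pytest.approx(
            25 + math.log(1 / 19), abs=1e-9
        )
        assert tacall.closed_form_ct(25, 1, 0.05) == pytest.approx(22.0556, abs=1e-3)

    @settings(max_examples=200, deadline=None)
    @given(
        st.floats(min_value=5, max_value=40),
        st.floats(min_value=0.1, max_value=3),
        st.floats(min_value=0.01, max_value=0.99),
    )
    def test_logistic_symmetry(self, m, k, q):
        lhs = tacall.closed_form_ct(m, k, q) + tacall.closed_form_ct(m, k, 1 - q)
        assert lhs == pytest.approx(2 * m, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(TacallError):
            tacall.closed_form_ct(25, 0, 0.05)
        with pytest.raises(TacallError):
            tacall.closed_form_ct(25, 1, 1.0)


class TestSimulateReaction:
    def test_non_amplified_draw_has_no_ct(self):
        cfg = noiseless_config(prevalence=0.0)
        rng = np.random.default_rng(0)
        r = tacall.simulate_reaction(cfg, rng)
        assert not r.label.amplified
        assert r.label.ct is None
        assert r.params["A"] is None

    def test_noiseless_crossing_matches_closed_form(self):
        """A worked example: the m=25, k=1 curve crosses at the closed form."""
        cfg = noiseless_config(prevalence=1.0, midpoint_range=(25, 25),
                               slope_range=(1, 1), seed=2)
        rng = np.random.default_rng(2)
        r = tacall.simulate_reaction(cfg, rng)
        assert r.label.amplified
        vals = tacall.normalize(tacall.standardize(r.trace))
        crossing = tacall.interpolated_crossing(
            vals, 1 + cfg.crossing_fraction * r.params["A"]
        )
        assert crossing == pytest.approx(r.label.ct, abs=0.1)
        assert r.label.ct == pytest.approx(tacall.closed_form_ct(25, 1, 0.05))

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_reactions=1)
        a = tacall.simulate_reaction(cfg, np.random.default_rng(5))
        b = tacall.simulate_reaction(cfg, np.random.default_rng(5))
        assert np.array_equal(a.trace.reporter, b.trace.reporter)
        assert np.array_equal(a.trace.rox, b.trace.rox)
        assert a.label == b.label
        assert a.params == b.params


class TestSimulateDataset:
    def test_amplified_fraction_near_prevalence(self):
        cfg = SimConfig(n_reactions=1000, prevalence=0.25, seed=17)
        _, labels = tacall.simulate_dataset(cfg)
        frac = sum(l.amplified for l in labels) / len(labels)
        assert 0.20 <= frac <= 0.30  # binomial 99% interval at n=1000

    def test_prevalence_zero_all_negative(self):
        cfg = SimConfig(n_reactions=50, prevalence=0.0, seed=1)
        _, labels = tacall.simulate_dataset(cfg)
        assert not any(l.amplified for l in labels)

    def test_prevalence_one_early_midpoints_all_amplified(self):
        cfg = SimConfig(n_reactions=50, prevalence=1.0,
                        midpoint_range=(12.0, 35.0), seed=1)
        _, labels = tacall.simulate_dataset(cfg)
        assert all(l.amplified for l in labels)
        assert all(l.ct <= cfg.cycles for l in labels)

    def test_seed_determinism_dataset_bytes(self, tmp_path):
        for run in ("a", "b"):
            cfg = SimConfig(n_reactions=60, seed=99)
            traces, labels = tacall.simulate_dataset(cfg)
            tacall.write_curves(traces, tmp_path / f"{run}_t.csv")
            tacall.write_labels(labels, tmp_path / f"{run}_l.csv")
        assert (tmp_path / "a_t.csv").read_bytes() == (tmp_path / "b_t.csv").read_bytes()
        assert (tmp_path / "a_l.csv").read_bytes() == (tmp_path / "b_l.csv").read_bytes()

    def test_late_amplifiers_present(self):
        """Defaults put a share of amplified reactions in the hard Ct 35-40 band."""
        cfg = SimConfig(n_reactions=2000, seed=3)
        _, labels = tacall.simulate_dataset(cfg)
        late = [l for l in labels if l.amplified and 35 <= l.ct <= 40]
        assert len(late) > 0

    def test_duplex_wells_share_well_id(self):
        cfg = SimConfig(n_reactions=400, seed=8)
        reactions = tacall.simulate_reactions(cfg)
        by_well = {}
        for r in reactions:
            by_well.setdefault(r.trace.well, []).append(r.trace)
        duplex = [v for v in by_well.values() if len(v) == 2]
        assert duplex, "expected some duplex wells at the default duplex share"
        for pair in duplex:
            assert {t.dye for t in pair} == {"FAM", "VIC"}

    def test_invalid_config_rejected(self):
        with pytest.raises(TacallError):
            SimConfig(n_reactions=0)
        with pytest.raises(TacallError):
            SimConfig(crossing_fraction=1.0)
        with pytest.raises(TacallError):
            SimConfig(prevalence=1.5)


class TestOracleEquivalence:
    def test_thousand_noiseless_curves_within_tenth_cycle(self):
        """Interpolated crossing vs closed form on 1,000 noiseless curves.

        Midpoints are drawn so the curve has a resolvable baseline phase
        (crossing beyond ~cycle 10); earlier crossings are inherently biased
        by the min-anchored normalization, not by the interpolation.
        """
        cfg = noiseless_config()
        rng = np.random.default_rng(424242)
        checked = 0
        worst = 0.0
        while checked < 1000:
            A = rng.uniform(*cfg.amplitude_range)
            m = rng.uniform(18.0, cfg.midpoint_range[1])
            k = rng.uniform(*cfg.slope_range)
            ct = tacall.closed_form_ct(m, k, cfg.crossing_fraction)
            if ct > cfg.cycles:
                continue
            c = np.arange(1, cfg.cycles + 1)
            signal = 1.0 + A / (1 + np.exp(-k * (c - m)))
            trace = tacall.FluorescenceTrace(
                "r", "FAM", cfg.rox_mean * signal, np.full(cfg.cycles, cfg.rox_mean)
            )
            vals = tacall.normalize(tacall.standardize(trace))
            crossing = tacall.interpolated_crossing(
                vals, 1 + cfg.crossing_fraction * A
            )
            worst = max(worst, abs(crossing - ct))
            checked += 1
        assert worst <= 0.1
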
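"""Slab pre-simulation: energy loss, scattering and interaction statistics."""

import numpy as np
import pytest

from pmmc import hu_to_mix, csda_range, residual_energy
from pmmc.presim import (CondensedStepConfig, highland_angle_sigma,
                         simulate_slab)


@pytest.fixture(scope="module")
def muscle(ramp):
    return hu_to_mix(ramp, 40)


def _hist_mean(probs, edges):
    c = 0.5 * (edges[:-1] + edges[1:])
    return float((probs * c).sum())


def test_thin_slab_mean_energy_loss(muscle):
    # mean dE within 2 standard errors of the closed-form CSDA loss
    t, e0, n = 0.5, 100.0, 8000
    rec = simulate_slab(muscle, t, e0, n, seed=1)
    expected = e0 - residual_energy(muscle, csda_range(muscle, e0) - t)
    c = 0.5 * (rec.de_edges[:-1] + rec.de_edges[1:])
    mean = _hist_mean(rec.h_energy_loss, rec.de_edges)
    var = float((rec.h_energy_loss * c ** 2).sum()) - mean ** 2
    sem = np.sqrt(var / n)
    assert abs(mean - expected) < 2.0 * sem


def test_rms_exit_angle_matches_highland(muscle):
    t, e0 = 1.0, 100.0
    rec = simulate_slab(muscle, t, e0, 20_000, seed=2)
    ac = 0.5 * (rec.angle_edges[:-1] + rec.angle_edges[1:])
    marg = rec.h_exit.sum(axis=1)
    rms = np.sqrt(float((marg * ac ** 2).sum()))
    # polar RMS of a 2-D Gaussian with projected sigma theta0 is sqrt(2)*theta0
    th0 = highland_angle_sigma(e0, t, muscle)
    assert rms == pytest.approx(np.sqrt(2.0) * th0, rel=0.05)


def test_thin_slab_limits(muscle):
    rec = simulate_slab(muscle, 1e-4, 150.0, 2000, seed=3)
    assert _hist_mean(rec.h_energy_loss, rec.de_edges) < 0.01
    ac = 0.5 * (rec.angle_edges[:-1] + rec.angle_edges[1:])
    assert np.sqrt(float((rec.h_exit.sum(axis=1) * ac ** 2).sum())) < 1e-3
    assert rec.p_elastic + rec.p_inelastic < 1e-4


def test_histograms_normalized_and_bounded(muscle):
    rec = simulate_slab(muscle, 0.2, 30.0, 3000, seed=4)
    for h in (rec.h_energy_loss, rec.h_exit, rec.h_process_depth):
        assert np.sum(h) == pytest.approx(1.0, abs=1e-9)
    assert rec.de_edges[-1] <= rec.incident_energy + 1e-9
    assert rec.disp_edges[-1] <= rec.thickness + 1e-9
    assert 0.0 <= rec.p_elastic and 0.0 <= rec.p_inelastic
    assert rec.p_elastic + rec.p_inelastic <= 1.0


def test_stopping_slab_records_full_energy(muscle):
    # slab thicker than the range: every proton stops inside, dE = E0
    rec = simulate_slab(muscle, 0.5, 15.0, 2000, seed=5)  # range ~ 0.25 cm
    assert rec.stopped_fraction == 1.0
    assert _hist_mean(rec.h_energy_loss, rec.de_edges) == pytest.approx(
        15.0, rel=1e-3)


def test_reproducibility_bit_identical(muscle):
    a = simulate_slab(muscle, 0.3, 50.0, 2000, seed=11)
    b = simulate_slab(muscle, 0.3, 50.0, 2000, seed=11)
    assert np.array_equal(a.h_energy_loss, b.h_energy_loss)
    assert np.array_equal(a.h_exit, b.h_exit)
    assert a.p_elastic == b.p_elastic and a.p_inelastic == b.p_inelastic


def test_invalid_arguments(muscle):
    with pytest.raises(ValueError):
        simulate_slab(muscle, -0.1, 50.0, 2000, seed=0)
    with pytest.raises(ValueError):
        simulate_slab(muscle, 0.1, -5.0, 2000, seed=0)
    with pytest.raises(ValueError):
        simulate_slab(muscle, 0.1, 50.0, 10, seed=0)


def test_highland_direct_evaluation(muscle):
    # independent hand evaluation of the same formula
    cfg = CondensedStepConfig()
    e, path = 158.0, 1.0
    m = 938.272
    et = e + m
    pv = (et * et - m * m) / et
    t = path * muscle.density * muscle.scatter_ratio / cfg.x0_water
    expected = 14.1 / pv * np.sqrt(t) * (1 + np.log10(t) / 9.0)
    assert highland_angle_sigma(e, path, muscle) == pytest.approx(
        expected, rel=1e-6)


def test_highland_scaling_laws(muscle):
    s1 = highland_angle_sigma(100.0, 1.0, muscle)
    s2 = highland_angle_sigma(100.0, 2.0, muscle)
    assert s2 / s1 == pytest.approx(np.sqrt(2.0), rel=0.05)
    assert highland_angle_sigma(200.0, 1.0, muscle) < s1
    with pytest.raises(ValueError):
        highland_angle_sigma(-1.0, 1.0, muscle)
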
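"""Forward model: integration, lead field, projection, eigenmodes."""

import numpy as np
import pytest

from rovingdcm import (
    StimulusInput,
    integrate_erp,
    make_synthetic_leadfield,
    principal_eigenmode,
    project_to_sensors,
)
from rovingdcm.leadfield import DEFAULT_MONTAGE, FRONTAL_CHANNELS


def test_zero_stimulus_gives_zero_response(space):
    r = integrate_erp(space, space.zeros(), 0, stimulus=StimulusInput(amplitude=0.0))
    assert np.all(r.v == 0)


def test_step_halving_convergence(space, grand_truth):
    """Halving the step changes every source's sp peak by < 0.1%."""
    r1 = integrate_erp(space, grand_truth, 0, dt_ms=1.0)
    r2 = integrate_erp(space, grand_truth, 0, dt_ms=0.5)
    for s in space.network.source_names:
        p1 = np.abs(r1.population(s, "sp")).max()
        p2 = np.abs(r2.population(s, "sp")).max()
        assert abs(p1 - p2) / p2 < 1e-3


def test_integration_is_reproducible(space, grand_truth):
    a = integrate_erp(space, grand_truth, 0).v
    b = integrate_erp(space, grand_truth, 0).v
    np.testing.assert_array_equal(a, b)


def test_step_above_one_ms_rejected(space):
    with pytest.raises(ValueError):
        integrate_erp(space, space.zeros(), 0, dt_ms=2.0)


def test_propagation_requires_forward_coupling(space, grand_truth):
    """STG/IFG respond only when the forward couplings are not suppressed."""
    r = integrate_erp(space, grand_truth, 0)
    assert np.abs(r.population("lSTG", "sp")).max() > 1e-3
    assert np.abs(r.population("lIFG", "sp")).max() > 1e-3
    cut = grand_truth.copy()
    cut[space.group("a_fwd")] = -30.0
    r0 = integrate_erp(space, cut, 0)
    assert np.abs(r0.population("lIFG", "sp")).max() < 1e-9
    assert np.abs(r0.population("lA1", "ss")).max() > 1e-2  # input still arrives


def test_projection_linearity(space, grand_truth, leadfield):
    r = integrate_erp(space, grand_truth, 0)
    erp = project_to_sensors(r, leadfield)
    r2 = integrate_erp(space, grand_truth, 0)
    r2.v = 2.0 * r2.v
    erp2 = project_to_sensors(r2, leadfield)
    np.testing.assert_allclose(erp2.data, 2.0 * erp.data, rtol=1e-12)
    r0 = integrate_erp(space, grand_truth, 0)
    r0.v = 0.0 * r0.v
    assert np.all(project_to_sensors(r0, leadfield).data == 0)


def test_projection_single_source_reproduces_leadfield_column(space, grand_truth, leadfield):
    r = integrate_erp(space, grand_truth, 0)
    r.v = np.zeros_like(r.v)
    j = space.network.source_index("rSTG")
    r.v[j, 1, :] = 1.0  # unit sp activity, no dp
    erp = project_to_sensors(r, leadfield)
    np.testing.assert_allclose(erp.data[:, 0], leadfield.gain[:, j], rtol=1e-12)


class TestSyntheticLeadfield:
    def test_shape_and_determinism(self, network):
        lf1 = make_synthetic_leadfield(network=network, seed=5)
        lf2 = make_synthetic_leadfield(network=network, seed=5)
        assert lf1.gain.shape == (20, 6)
        np.testing.assert_array_equal(lf1.gain, lf2.gain)
        lf3 = make_synthetic_leadfield(network=network, seed=6)
        assert not np.array_equal(lf1.gain, lf3.gain)

    def test_montage(self, leadfield):
        assert leadfield.channels == DEFAULT_MONTAGE
        assert len(leadfield.channels) == 20

    def test_frontal_source_loads_frontal_channels(self, network):
        lf = make_synthetic_leadfield(network=network, seed=0)
        j = network.source_index("lIFG")
        best = lf.channels[int(np.argmax(np.abs(lf.gain[:, j])))]
        assert best in FRONTAL_CHANNELS

    def test_no_dead_channels(self, leadfield):
        assert np.all(np.abs(leadfield.gain).max(axis=1) > 0)

    def test_empty_montage_rejected(self, network):
        with pytest.raises(ValueError):
            make_synthetic_leadfield(montage=(), network=network)


class TestPrincipalEigenmode:
    def test_rank_one_recovery(self, rng):
        w = rng.standard_normal(12)
        tau = np.sin(np.linspace(0, 3 * np.pi, 100))
        temporal, weights = principal_eigenmode(np.outer(w, tau))
        # recovered up to sign/scale; align signs before comparing
        corr = np.corrcoef(temporal, tau)[0, 1]
        assert abs(corr) > 1 - 1e-10
        assert weights[np.argmax(np.abs(weights))] > 0

    def test_two_mode_toy_matches_svd(self, rng):
        u = np.linalg.qr(rng.standard_normal((8, 2)))[0]
        t1 = np.sin(np.linspace(0, 2 * np.pi, 50))
        t2 = np.cos(np.linspace(0, 6 * np.pi, 50))
        data = 3.0 * np.outer(u[:, 0], t1) + 1.0 * np.outer(u[:, 1], t2)
        temporal, weights = principal_eigenmode(data)
        uu, ss, vv = np.linalg.svd(data)
        assert np.allclose(np.abs(weights @ uu[:, 0]), 1.0, atol=1e-10)
        assert np.allclose(np.abs(temporal), ss[0] * np.abs(vv[0]), atol=1e-8)

    def test_single_channel(self):
        x = np.array([[1.0, -2.0, 3.0]])
        temporal, weights = principal_eigenmode(x)
        np.testing.assert_allclose(temporal, x[0], atol=1e-12)
        np.testing.assert_allclose(weights, [1.0])

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            principal_eigenmode(np.zeros((3, 10)))
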
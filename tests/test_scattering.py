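"""Scattering transform: shape contracts, frame quality, oracle equivalence,
invariance and stability properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aepkit import scattering as sc
from aepkit.errors import ConfigurationError, IntegrityError


def test_abr_network_shape_contract(abr_network):
    n0, n1, n2, total = sc.count_paths(abr_network)
    assert (n0, total) == (1, 40)
    assert total == 1 + n1 + n2
    assert abr_network.n_windows == 15


def test_amlr_network_shape_contract(amlr_network):
    n0, n1, n2, total = sc.count_paths(amlr_network)
    assert (n0, total) == (1, 65)
    assert total == 1 + n1 + n2
    assert amlr_network.n_windows == 7


def test_scatter_tensor_shapes(abr_network, amlr_network):
    rng = np.random.default_rng(0)
    t_abr = sc.scatter(rng.normal(size=450), abr_network)
    assert t_abr.coefficients.shape == (40, 15)
    t_amlr = sc.scatter(rng.normal(size=420), amlr_network)
    assert t_amlr.coefficients.shape == (65, 7)
    assert len(sc.scale_average(t_abr)) == 40
    assert len(sc.scale_average(t_amlr)) == 65
    combined = np.concatenate([sc.scale_average(t_abr),
                               sc.scale_average(t_amlr)])
    assert len(combined) == 105


def test_raw_tensor_nonnegative_and_order_structure(abr_network):
    rng = np.random.default_rng(1)
    t = sc.scatter(rng.normal(size=450), abr_network)
    assert (t.coefficients >= 0).all()
    orders = [p[0] for p in t.path_index]
    assert orders[0] == 0 and orders.count(0) == 1
    assert sorted(orders) == orders
    # order-1 centre frequencies strictly decreasing
    l1 = [p[1] for p in t.path_index if p[0] == 1]
    assert all(a > b for a, b in zip(l1, l1[1:]))
    # order-2 paths satisfy the bandwidth pruning rule
    bank1 = abr_network.bank1
    bw_of = dict(zip(bank1.centers_cps * abr_network.fs_hz,
                     bank1.bandwidths_cps * abr_network.fs_hz))
    for order, lam1, lam2 in t.path_index:
        if order == 2:
            assert lam2 < sc._ORDER2_BW_FACTOR * bw_of[lam1]


def test_littlewood_paley_bounds(abr_network, amlr_network):
    """Frame quality: LP sum <= 1 + 1e-9 everywhere and >= 0.5 over the
    band the wavelets cover."""
    for net in (abr_network, amlr_network):
        for bank in (net.bank1, net.bank2):
            f = np.linspace(0.0, 0.5, 8192, endpoint=False)
            lp = sc.littlewood_paley(bank, net.sigma_phi_cps, 8192)
            assert lp.max() <= 1 + 1e-9
            band = (f >= bank.centers_cps.min()) & (f <= bank.centers_cps.max())
            assert lp[band].min() >= 0.5


def test_minimal_network_single_wavelet_banks():
    """A short enough invariance scale admits exactly one wavelet per Q=1
    bank (the scaling filter covers everything below the mother wavelet)."""
    net = sc.build_network(1000.0, 64, 0.00565, (1, 1))
    assert net.bank1.n_filters == 1
    assert net.bank2.n_filters == 1
    assert sc.count_paths(net)[3] >= 2


def test_count_paths_matches_bruteforce_enumeration():
    """Order-2 count equals exhaustive enumeration of admissible pairs."""
    for cfg in (sc.ABR_CONFIG, sc.AMLR_CONFIG,
                dict(fs_hz=1000.0, signal_length=256, invariance_scale_s=0.05)):
        net = sc.build_network(cfg["fs_hz"], cfg["signal_length"],
                               cfg["invariance_scale_s"])
        n2 = 0
        for bw1 in net.bank1.bandwidths_cps:
            for f2 in net.bank2.centers_cps:
                if f2 < sc._ORDER2_BW_FACTOR * bw1:
                    n2 += 1
        counts = sc.count_paths(net)
        assert counts[2] == n2
        assert counts[3] == 1 + counts[1] + n2


def test_build_network_rejects_bad_configs():
    with pytest.raises(ConfigurationError, match="longer than the signal"):
        sc.build_network(30000.0, 450, 0.5)
    with pytest.raises(ConfigurationError, match="exceed one sample"):
        sc.build_network(100.0, 450, 0.001)


def test_zero_signal_gives_zero_tensor(abr_network):
    t = sc.scatter(np.zeros(450), abr_network)
    assert np.abs(t.coefficients).max() == 0.0


def test_fft_filtering_equals_direct_circular_convolution():
    """FFT-domain filtering matches O(n^2) circular convolution <= 1e-8."""
    rng = np.random.default_rng(7)
    for n in (16, 33, 64):
        x = rng.normal(size=n)
        response = rng.normal(size=n) + 1j * rng.normal(size=n)
        h = np.fft.ifft(response)
        direct = np.array([sum(x[m] * h[(k - m) % n] for m in range(n))
                           for k in range(n)])
        fast = sc.apply_filter_fft(x, response)
        assert np.abs(fast - direct).max() <= 1e-8


def test_sinusoid_excites_matching_first_order_path(abr_network):
    """A sinusoid at a first-bank centre dominates that wavelet's path."""
    for k in (0, 5, 15, 30):
        fc = abr_network.bank1.centers_cps[k]
        x = np.cos(2 * np.pi * fc * np.arange(450))
        t = sc.scatter(x, abr_network)
        o1 = t.coefficients[1:1 + abr_network.bank1.n_filters].mean(axis=1)
        assert int(o1.argmax()) == k


def test_log_coeffs_values_and_floor(abr_network):
    rng = np.random.default_rng(2)
    t = sc.scatter(rng.normal(size=450), abr_network)
    ones = sc.ScatteringTensor(np.ones_like(t.coefficients),
                               list(t.path_index), t.window_times_s)
    assert np.all(sc.log_coeffs(ones).coefficients == 0.0)
    e = sc.ScatteringTensor(np.full_like(t.coefficients, np.e),
                            list(t.path_index), t.window_times_s)
    assert sc.log_coeffs(e).coefficients == pytest.approx(1.0)
    zeros = sc.ScatteringTensor(np.zeros_like(t.coefficients),
                                list(t.path_index), t.window_times_s)
    logged = sc.log_coeffs(zeros, floor=1e-12)
    assert logged.coefficients == pytest.approx(np.log(1e-12))
    assert logged.coefficients[0, 0] == pytest.approx(-27.631, abs=1e-3)
    neg = sc.ScatteringTensor(-np.ones_like(t.coefficients),
                              list(t.path_index), t.window_times_s)
    with pytest.raises(IntegrityError):
        sc.log_coeffs(neg)


def test_scale_average_is_row_mean(abr_network):
    rng = np.random.default_rng(3)
    t = sc.scatter(rng.normal(size=450), abr_network)
    oracle = np.array([sum(row) / len(row) for row in t.coefficients])
    assert sc.scale_average(t) == pytest.approx(oracle, abs=1e-12)
    const = sc.ScatteringTensor(np.tile(t.coefficients[:, :1], (1, 15)),
                                list(t.path_index), t.window_times_s)
    assert sc.scale_average(const) == pytest.approx(const.coefficients[:, 0])


def test_energy_by_order_arithmetic():
    tensor = sc.ScatteringTensor(
        coefficients=np.array([[2.0], [1.0], [1.0]]),
        path_index=[(0, None, None), (1, 100.0, None), (2, 100.0, 10.0)],
        window_times_s=np.array([0.0]))
    assert sc.energy_by_order(tensor) == pytest.approx([4 / 6, 1 / 6, 1 / 6])
    only0 = sc.ScatteringTensor(np.array([[1.0], [0.0], [0.0]]),
                                tensor.path_index, tensor.window_times_s)
    assert sc.energy_by_order(only0) == pytest.approx([1.0, 0.0, 0.0])
    with pytest.raises(ZeroDivisionError):
        sc.energy_by_order(sc.ScatteringTensor(
            np.zeros((3, 1)), tensor.path_index, tensor.window_times_s))


def test_energy_concentration_on_synthetic_aeps(abr_network, amlr_network,
                                                small_cohort):
    """Orders 0-1 hold >= 99% of the scattering energy of AEP-like input."""
    fracs = []
    for rec in small_cohort.records_of("ABR")[:30]:
        e = sc.energy_by_order(sc.scatter(rec.samples, abr_network))
        fracs.append(e[0] + e[1])
    for rec in small_cohort.records_of("AMLR")[:30]:
        e = sc.energy_by_order(sc.scatter(rec.samples[:420], amlr_network))
        fracs.append(e[0] + e[1])
    assert np.mean(fracs) >= 0.99


def test_order2_energy_below_order1(abr_network, small_cohort):
    for rec in small_cohort.records_of("ABR")[:10]:
        e = sc.energy_by_order(sc.scatter(rec.samples, abr_network))
        assert e[2] <= e[1]


def test_non_expansiveness(abr_network):
    """||S(x) - S(y)|| <= ||x - y|| on random signal pairs."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        x = rng.normal(size=450)
        y = x + rng.normal(scale=rng.uniform(0.01, 2.0), size=450)
        dist = np.linalg.norm(sc.scatter(x, abr_network).coefficients
                              - sc.scatter(y, abr_network).coefficients)
        assert dist <= np.linalg.norm(x - y) + 1e-12


def test_translation_invariance_degradation(abr_network, abr_record):
    """Scale-averaged features move < 5% in relative l2 for shifts up to
    0.1 * T * fs."""
    base = sc.scale_average(sc.scatter(abr_record.samples, abr_network))
    max_shift = int(0.1 * abr_network.t_samples)
    for shift in range(2, max_shift + 1, 4):
        shifted = np.roll(abr_record.samples, shift)
        v = sc.scale_average(sc.scatter(shifted, abr_network))
        rel = np.linalg.norm(v - base) / np.linalg.norm(base)
        assert rel < 0.05, shift


def test_scatter_rejects_length_mismatch(abr_network):
    with pytest.raises(ValueError, match="length"):
        sc.scatter(np.zeros(449), abr_network)


def test_deterministic_construction():
    a = sc.build_network(**sc.ABR_CONFIG)
    b = sc.build_network(**sc.ABR_CONFIG)
    np.testing.assert_array_equal(a.bank1.centers_cps, b.bank1.centers_cps)
    np.testing.assert_array_equal(a.bank1.gains, b.bank1.gains)
    x = np.sin(np.arange(450) * 0.1)
    np.testing.assert_array_equal(sc.scatter(x, a).coefficients,
                                  sc.scatter(x, b).coefficients)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_feature_vector_finite_and_sized(abr_network, seed):
    rng = np.random.default_rng(seed)
    v = sc.feature_vector(rng.normal(size=450), abr_network)
    assert v.shape == (40,)
    assert np.all(np.isfinite(v))
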
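import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from spingroup import (
    InsufficientDataError,
    RegistrationConfig,
    build_support_matrix,
    chi_square_pair,
    distance_matrix,
    register,
    robustness,
)

from conftest import make_peaklist, simulated_list
from oracles import brute_chi_prob, brute_robustness, brute_support_sets


def random_list(rng, n, spread=(0.1, 1.0)):
    shifts = np.column_stack([rng.normal(0, s, n) for s in spread])
    return make_peaklist(shifts.tolist())


# --- distance matrix -------------------------------------------------------


def test_distance_matrix_basics():
    pl = make_peaklist([[0.0, 0.0], [3.0, 4.0], [3.0, 4.0]])
    d = distance_matrix(pl)
    assert d[0, 1] == pytest.approx(5.0)
    assert d[1, 2] == 0.0
    assert np.allclose(d, d.T)
    assert np.all(np.diag(d) == 0)


def test_distance_matrix_matches_brute_force(rng):
    pl = random_list(rng, 6)
    d = distance_matrix(pl)
    for a in range(6):
        for b in range(6):
            expect = math.dist(pl.comparable_shifts(a), pl.comparable_shifts(b))
            assert d[a, b] == pytest.approx(expect, abs=1e-12)


def test_distance_matrix_needs_two_peaks():
    with pytest.raises(InsufficientDataError):
        distance_matrix(make_peaklist([[1.0, 2.0]]))


# --- chi-square statistic --------------------------------------------------


def test_chi_square_identical_peaks():
    pl = make_peaklist([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
    stat, prob = chi_square_pair(pl, pl, 0, 1, 2, 3, stds=(0.01, 0.01))
    assert stat == 0.0
    assert prob == 1.0


def test_chi_square_one_dimension_arithmetic():
    pl_in = make_peaklist([[0.0], [0.04]])
    pl_root = make_peaklist([[0.0], [0.0]])
    stat, _ = chi_square_pair(pl_in, pl_root, 1, 1, 0, 0, stds=(0.01,), std_factor=2.0)
    assert stat == pytest.approx((0.04 / 0.02) ** 2)  # 4.0


def test_chi_square_prob_df2_closed_form():
    # stat 4.0 at df=2: survival probability is exp(-2)
    pl_in = make_peaklist([[0.0, 0.0], [0.04, 0.0]])
    pl_root = make_peaklist([[0.0, 0.0], [0.0, 0.0]])
    stat, prob = chi_square_pair(pl_in, pl_root, 1, 1, 0, 0, stds=(0.01, 1e9), std_factor=2.0)
    assert stat == pytest.approx(4.0)
    assert prob == pytest.approx(math.exp(-2.0), rel=1e-9)


def test_zero_std_instructs_flooring():
    pl = make_peaklist([[0.0, 0.0], [1.0, 1.0]])
    with pytest.raises(ValueError, match="floor"):
        chi_square_pair(pl, pl, 0, 1, 1, 0, stds=(0.0, 0.1))


# --- support matrix --------------------------------------------------------


def test_identical_lists_pairwise_diagonal_support(rng):
    pl = random_list(rng, 5)
    sm = build_support_matrix(pl, pl, stds=(0.01, 0.01), mode="pairwise")
    for i in range(5):
        assert {(m, m) for m in range(5) if m != i} <= sm.support(i, i)


def test_self_mode_excludes_identity_mappings(rng):
    pl = random_list(rng, 6, spread=(0.01, 0.01))
    sm = build_support_matrix(pl, pl, stds=(0.1, 0.1), mode="self")
    assert all(i != j for i, j in sm.entries)
    for key, members in sm.entries.items():
        assert all(m != n for m, n in members)
        assert key not in members


@pytest.mark.parametrize("mode", ["pairwise", "self"])
def test_support_sets_match_brute_force(rng, mode):
    cfg = RegistrationConfig()
    for _ in range(25):
        n = int(rng.integers(3, 8))
        pl_in = random_list(rng, n, spread=(0.05, 0.5))
        pl_root = pl_in if mode == "self" else random_list(rng, n, spread=(0.05, 0.5))
        stds = (float(rng.uniform(0.01, 0.1)), float(rng.uniform(0.05, 0.5)))
        sm = build_support_matrix(pl_in, pl_root, stds, cfg, mode=mode)
        brute = brute_support_sets(pl_in, pl_root, stds, cfg.tolerance_units, mode)
        for key, members in brute.items():
            assert sm.support(*key) == members


# --- robustness ------------------------------------------------------------


def test_robustness_empty_support_is_zero(rng):
    pl = random_list(rng, 4)
    sm = build_support_matrix(pl, pl, stds=(1e-6, 1e-6), mode="self")
    assert robustness(sm, 0, 1, lambda m, n: 1.0) == 0.0


def test_robustness_identical_lists_hand_computed():
    # two identical 3-peak lists, pairwise: SS_{0,0} = {(1,1),(2,2)},
    # SS_{1,1} = {(0,0),(2,2)}; each Jaccard is 1/3 and each probability 1
    # (zero differences), so robustness(0,0) = 2/3.
    pl = make_peaklist([[1.0, 5.0], [3.0, 8.0], [9.0, 2.0]])
    sm = build_support_matrix(pl, pl, stds=(0.01, 0.01), mode="pairwise")
    assert sm.support(0, 0) == {(1, 1), (2, 2)}
    assert robustness(sm, 0, 0, lambda m, n: 1.0) == pytest.approx(2.0 / 3.0)


def test_robustness_matches_brute_force(rng):
    cfg = RegistrationConfig()
    for _ in range(15):
        n = int(rng.integers(4, 8))
        pl = random_list(rng, n, spread=(0.05, 0.5))
        stds = (0.05, 0.3)
        sm = build_support_matrix(pl, pl, stds, cfg, mode="self")
        brute = brute_support_sets(pl, pl, stds, cfg.tolerance_units, "self")
        for (i, j), _members in brute.items():
            got = robustness(
                sm, i, j, lambda m, n: brute_chi_prob(pl, pl, i, j, m, n, stds, 2.0)
            )
            want = brute_robustness(brute, pl, pl, i, j, stds, 2.0)
            assert got == pytest.approx(want, abs=1e-12)


# --- full registration -----------------------------------------------------


def shifted_copy(pl, delta):
    shifts = [
        [s + delta.get(d, 0.0) for d, s in enumerate(p.shifts)]
        for p in pl
    ]
    return make_peaklist(shifts, comparable_dims=pl.comparable_dims)


def test_pairwise_recovers_known_translation(rng):
    base = simulated_list(n_res=60, sigma_h=0.0, sigma_c=0.0, sigma_n=0.0)
    jitter = np.random.default_rng(5)
    shifts = [
        [s + jitter.normal(0, 0.0005 if d == 0 else 0.005) for d, s in enumerate(p.shifts)]
        for p in base
    ]
    root = make_peaklist(shifts, comparable_dims=base.comparable_dims)
    root = shifted_copy(root, {0: 0.05})
    res = register(base, root, mode="pairwise")
    assert res.stats.offsets[0] == pytest.approx(0.05, abs=0.002)
    assert res.stats.offsets[1] == pytest.approx(0.0, abs=0.02)


def test_pairwise_translation_equivariance(rng):
    # random (system-free) lists: the best mapping is unambiguous, so the
    # recovered statistics respond to a pure translation exactly
    base = random_list(rng, 40, spread=(0.6, 4.0))
    jitter = np.column_stack([rng.normal(0, 0.002, 40), rng.normal(0, 0.02, 40)])
    root = make_peaklist((np.array([p.shifts for p in base]) + jitter).tolist())
    res0 = register(base, root, mode="pairwise")
    shifted = shifted_copy(base, {0: 0.013, 1: -0.21})
    res1 = register(shifted, root, mode="pairwise")
    assert res1.stats.offsets[0] - res0.stats.offsets[0] == pytest.approx(-0.013, abs=1e-9)
    assert res1.stats.offsets[1] - res0.stats.offsets[1] == pytest.approx(0.21, abs=1e-9)
    assert np.allclose(res1.stats.stds, res0.stats.stds, atol=1e-9)


def test_self_registration_recovers_injected_sigma():
    """Mean recovered std over seeds within 15% of the injected sigma."""
    sh, sn = 0.004, 0.04
    rec = []
    for seed in range(3):
        pl = simulated_list(
            n_res=90, table_seed=40 + seed, noise_seed=50 + seed,
            sigma_h=sh, sigma_c=sn, sigma_n=sn,
        )
        res = register(pl, mode="self")
        rec.append(res.stats.stds)
    mean = np.mean(rec, axis=0)
    assert abs(mean[0] / sh - 1) < 0.15
    assert abs(mean[1] / sn - 1) < 0.15


def test_self_registration_zero_variance_list():
    pl = simulated_list(n_res=40, sigma_h=0.0, sigma_c=0.0, sigma_n=0.0)
    res = register(pl, mode="self")
    assert res.mode == "self"
    assert all(o == 0.0 for o in res.stats.offsets)
    assert all(s <= 1e-6 for s in res.stats.stds)
    # every within-spin-system pair (2-peak systems) is mapped
    truth = pl.truth_groups()
    two_peak_systems = {
        g for g in set(truth) if truth.count(g) == 2
    }
    mapped_groups = {truth[m] for m, n in res.mapped_pairs if truth[m] == truth[n]}
    assert two_peak_systems <= mapped_groups


def test_self_offsets_always_zero_and_trace_converges():
    pl = simulated_list(n_res=70, sigma_h=0.005, sigma_c=0.05, sigma_n=0.05)
    cfg = RegistrationConfig()
    res = register(pl, mode="self", cfg=cfg)
    assert res.stats.offsets == (0.0, 0.0)
    assert res.converged
    last, prev = np.array(res.trace[-1]), np.array(res.trace[-2])
    assert np.max(np.abs(last - prev) / prev) < cfg.convergence_tol


def test_recovered_std_monotone_in_injected_noise():
    sigmas = [0.001, 0.003, 0.006, 0.012, 0.024]
    means = []
    for s in sigmas:
        vals = [
            register(
                simulated_list(
                    n_res=70, table_seed=7 + r, noise_seed=70 + r,
                    sigma_h=s, sigma_c=10 * s, sigma_n=10 * s,
                ),
                mode="self",
            ).stats.stds[0]
            for r in range(3)
        ]
        means.append(np.mean(vals))
    rho, _ = spearmanr(sigmas, means)
    assert rho > 0.999  # strictly increasing ranks


def test_register_requires_two_peaks():
    pl = make_peaklist([[1.0, 2.0]])
    with pytest.raises(InsufficientDataError):
        register(pl, mode="self")
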
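"""Generator correctness: CTMC sojourn laws, renewal mixtures, titration and
FRAP closed forms, and seed determinism."""

import numpy as np
import pytest
from scipy import stats

from pfkinetics import synthetic_data as syn


# --------------------------------------------------------------------------- #
# kinetic scheme validation
# --------------------------------------------------------------------------- #

def test_scheme_generator_rows_sum_to_zero(dna_scheme):
    q = dna_scheme.rate_matrix(5.0)
    assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
    assert np.all(q[~np.eye(3, dtype=bool)] >= 0)


def test_scheme_concentration_scaling(dna_scheme):
    q2 = dna_scheme.rate_matrix(2.0)
    q10 = dna_scheme.rate_matrix(10.0)
    # only the binding edge U->B scales with concentration
    assert q10[0, 1] == pytest.approx(5.0 * q2[0, 1])
    assert q10[1, 0] == pytest.approx(q2[1, 0])


def test_scheme_rejects_single_class():
    with pytest.raises(ValueError, match="both observable classes"):
        syn.KineticScheme(
            ["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]),
            np.zeros((2, 2), dtype=int), {"a": "low", "b": "low"},
        )


def test_scheme_rejects_negative_rates():
    with pytest.raises(ValueError):
        syn.KineticScheme(
            ["a", "b"], np.array([[0.0, -1.0], [1.0, 0.0]]),
            np.zeros((2, 2), dtype=int), {"a": "low", "b": "high"},
        )


# --------------------------------------------------------------------------- #
# CTMC trace simulation
# --------------------------------------------------------------------------- #

def test_zero_concentration_never_binds(dna_scheme):
    """With the binding edge scaled by c = 0, a trace started unbound stays low."""
    tr = syn.simulate_ctmc_trace(
        dna_scheme, 0.0, 60.0, 0.1, seed=1, initial_state="U"
    )
    assert np.all(tr.true_class_path == 0)


def test_ctmc_seed_determinism(dna_scheme):
    a = syn.simulate_ctmc_trace(dna_scheme, 5.0, 60.0, 0.1, seed=42)
    b = syn.simulate_ctmc_trace(dna_scheme, 5.0, 60.0, 0.1, seed=42)
    assert np.array_equal(a.true_state_path, b.true_state_path)
    assert np.array_equal(a.signal, b.signal)
    c = syn.simulate_ctmc_trace(dna_scheme, 5.0, 60.0, 0.1, seed=43)
    assert not np.array_equal(a.signal, c.signal)


def test_bound_state_mean_dwell_matches_total_exit_rate(dna_scheme):
    """Mean sojourn in the bound high state is 1 / (k_off + k_struct_out)."""
    rng = np.random.default_rng(5)
    dwells = []
    for _ in range(60):
        et, st = syn.gillespie_path(dna_scheme, 5.0, 400.0, rng)
        d = np.diff(et)
        dwells.append(d[st[:-1] == 1])  # interior sojourns of state B
    dwells = np.concatenate(dwells)
    expected = 1.0 / (0.58 + 0.036 * 25.0 / 75.0)
    sem = dwells.std() / np.sqrt(dwells.size)
    assert dwells.size > 2000
    assert abs(dwells.mean() - expected) < 2.0 * sem


def test_ctmc_sojourn_times_are_exponential(dna_scheme):
    """Kolmogorov-Smirnov check of the state-B sojourn law at fixed seed."""
    rng = np.random.default_rng(12)
    dwells = []
    for _ in range(80):
        et, st = syn.gillespie_path(dna_scheme, 5.0, 400.0, rng)
        d = np.diff(et)
        dwells.append(d[st[:-1] == 1])
    dwells = np.concatenate(dwells)
    total_exit = 0.58 + 0.036 * 25.0 / 75.0
    ks = stats.kstest(dwells, "expon", args=(0, 1.0 / total_exit))
    assert ks.pvalue > 0.01


def test_aggregated_two_state_class_dwell_is_biexponential():
    """With two interconnected high states the class dwell survival follows
    the two-eigenvalue phase-type form of the sub-generator."""
    # A(low) -> B(high) <-> C(high); both B and C can exit to A
    base = np.array(
        [
            [0.0, 1.0, 0.0],
            [0.5, 0.0, 0.3],
            [0.05, 0.2, 0.0],
        ]
    )
    scheme = syn.KineticScheme(
        ["A", "B", "C"], base, np.zeros((3, 3), dtype=int),
        {"A": "low", "B": "high", "C": "high"},
    )
    rng = np.random.default_rng(3)
    # collect complete high-class sojourns with their entry state
    samples = []
    for _ in range(60):
        et, st = syn.gillespie_path(scheme, 1.0, 600.0, rng)
        edges = np.concatenate([et, [600.0]])
        cls = np.where(st == 0, 0, 1)
        k = 0
        while k < len(st):
            if cls[k] == 1:
                j = k
                while j < len(st) and cls[j] == 1:
                    j += 1
                if j < len(st):  # complete sojourn (not truncated by movie end)
                    samples.append((st[k], edges[j] - edges[k]))
                k = j
            else:
                k += 1
    entries = np.array([s[0] for s in samples])
    durs = np.array([s[1] for s in samples])
    # analytic survival: S(t) = alpha' exp(G t) 1 with G the high sub-generator
    g = np.array([[-(0.5 + 0.3), 0.3], [0.2, -(0.05 + 0.2)]])
    p_b = np.mean(entries == 1)
    alpha = np.array([p_b, 1.0 - p_b])
    from scipy.linalg import expm

    for t0 in (0.5, 1.0, 2.0, 5.0):
        s_analytic = alpha @ expm(g * t0) @ np.ones(2)
        s_emp = np.mean(durs > t0)
        se = np.sqrt(s_analytic * (1 - s_analytic) / durs.size)
        assert abs(s_emp - s_analytic) < 3.0 * max(se, 1e-3)


def test_ctmc_rejects_bad_arguments(dna_scheme):
    with pytest.raises(ValueError):
        syn.simulate_ctmc_trace(dna_scheme, 5.0, 0.05, 0.1, seed=0)
    with pytest.raises(ValueError):
        syn.simulate_ctmc_trace(dna_scheme, -1.0, 10.0, 0.1, seed=0)


def test_photobleaching_truncates_trace(dna_scheme):
    full = syn.simulate_ctmc_trace(dna_scheme, 5.0, 300.0, 0.1, seed=9)
    bleached = syn.simulate_ctmc_trace(
        dna_scheme, 5.0, 300.0, 0.1, seed=9, bleach_rate=0.05
    )
    assert bleached.times.size < full.times.size
    assert bleached.meta["bleach_time_s"] is not None


def test_discretization_modes_agree_on_slow_dynamics():
    scheme = syn.reb1_nucleosome_scheme()
    maj = syn.simulate_ctmc_trace(scheme, 5.0, 600.0, 1.0, seed=2,
                                  discretize="majority")
    mid = syn.simulate_ctmc_trace(scheme, 5.0, 600.0, 1.0, seed=2,
                                  discretize="midpoint")
    # slow kinetics: the two conventions differ only at sojourn boundaries
    assert np.mean(maj.true_class_path != mid.true_class_path) < 0.05


# --------------------------------------------------------------------------- #
# renewal trace simulation
# --------------------------------------------------------------------------- #

def test_renewal_single_component_dwell_mean():
    spec = syn.RenewalSpec((1.0,), (1.0,), (1.0,), (1.0,))
    rng = np.random.default_rng(8)
    means = [syn._draw_mixture((1.0,), (1.0,), rng) for _ in range(20000)]
    m = np.mean(means)
    assert abs(m - 1.0) < 3.0 * np.std(means) / np.sqrt(len(means))


def test_renewal_mixture_dwell_mean_matches_formula():
    """High-state mixture 0.75 Exp(0.58) + 0.25 Exp(0.036): mean a1/k1 + a2/k2."""
    spec = syn.RenewalSpec(
        low_rates=(0.5,), low_amps=(1.0,),
        high_rates=(0.58, 0.036), high_amps=(0.75, 0.25),
    )
    expected = 0.75 / 0.58 + 0.25 / 0.036
    rng = np.random.default_rng(13)
    draws = np.array(
        [syn._draw_mixture(spec.high_rates, spec.high_amps, rng)
         for _ in range(30000)]
    )
    sem = draws.std() / np.sqrt(draws.size)
    assert abs(draws.mean() - expected) < 3.0 * sem
    assert spec.mean_dwell("high") == pytest.approx(expected)


def test_renewal_trace_alternates_and_is_deterministic():
    spec = syn.RenewalSpec((0.5,), (1.0,), (1.0,), (1.0,))
    a = syn.simulate_renewal_trace(spec, 200.0, 0.1, seed=3)
    b = syn.simulate_renewal_trace(spec, 200.0, 0.1, seed=3)
    assert np.array_equal(a.signal, b.signal)
    assert set(np.unique(a.true_class_path)) <= {0, 1}


def test_renewal_undersampling_warns():
    spec = syn.RenewalSpec((100.0,), (1.0,), (100.0,), (1.0,))
    with pytest.warns(UserWarning, match="undersampled"):
        syn.simulate_renewal_trace(spec, 10.0, 1.0, seed=0)


def test_renewal_amplitudes_recovered():
    """Fraction of fast-component draws matches the requested amplitude."""
    rng = np.random.default_rng(21)
    n = 30000
    draws = np.array(
        [syn._draw_mixture((0.58, 0.036), (0.75, 0.25), rng) for _ in range(n)]
    )
    # classify by posterior odds at the known rates; threshold where the
    # component densities cross
    k1, k2, a1 = 0.58, 0.036, 0.75
    t_star = np.log((a1 * k1) / ((1 - a1) * k2)) / (k1 - k2)
    frac_fast = np.mean(draws < t_star)
    # expected fraction below the crossing under the mixture
    expect = a1 * (1 - np.exp(-k1 * t_star)) + (1 - a1) * (1 - np.exp(-k2 * t_star))
    se = np.sqrt(expect * (1 - expect) / n)
    assert abs(frac_fast - expect) < 3.0 * se


# --------------------------------------------------------------------------- #
# titration and FRAP
# --------------------------------------------------------------------------- #

def test_titration_half_saturation_identity():
    spec = syn.TitrationSpec(
        s_half=2.2, concentrations=np.array([2.2]), f0=0.85, f1=0.20
    )
    df = syn.simulate_titration(spec, seed=0)
    assert df["response"].iloc[0] == pytest.approx((0.85 + 0.20) / 2.0)


def test_titration_saturation_tail_bound():
    spec = syn.TitrationSpec(
        s_half=2.2, concentrations=np.array([2.2e4]), f0=0.85, f1=0.20
    )
    r = syn.simulate_titration(spec, seed=0)["response"].iloc[0]
    assert abs(r - 0.20) < 1.1e-4 * abs(0.20 - 0.85)


def test_titration_rejects_negative_concentration():
    with pytest.raises(ValueError):
        syn.TitrationSpec(s_half=1.0, concentrations=np.array([-1.0]))


def test_frap_half_life_definition():
    spec = syn.FRAPSpec(t_half=25.8, depth=0.8, mobile=1.0, noise_sd=0.0)
    r = spec.recovery(np.array([25.8]))[0]
    # at one half-life, half of the bleached depth has recovered
    assert r == pytest.approx(1.0 - 0.8 + 0.8 * 0.5)
    assert spec.t_half / spec.tau == pytest.approx(np.log(2.0), abs=1e-12)


def test_frap_immobile_limit_flat():
    spec = syn.FRAPSpec(t_half=10.0, depth=0.8, mobile=0.0, noise_sd=0.0,
                        n_postbleach=20)
    df = syn.simulate_frap(spec, seed=0)
    post = df[df["postbleach"] == 1]
    ratio = post["bleached_mean"] / post["unbleached_mean"]
    assert np.allclose(ratio, 1.0 - 0.8, atol=1e-12)


def test_frap_rejects_bad_half_life():
    with pytest.raises(ValueError):
        syn.FRAPSpec(t_half=-1.0)
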
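"""Dwell extraction book-keeping, windowed mixture MLE against closed forms
and a grid-search oracle, and likelihood-ratio model selection."""

import numpy as np
import pytest

from pfkinetics import dwell_analysis as da
from pfkinetics import synthetic_data as syn


def draw_truncated_mixture(rng, n, rates, amps, t_min=0.0):
    """Mixture draws conditioned on t >= t_min (rejection-free via inverse CDF
    per component is biased; use simple rejection, fast at these rates)."""
    out = []
    while len(out) < n:
        comp = rng.random(n) < amps[0]
        t = np.where(
            comp, rng.exponential(1.0 / rates[0], n),
            rng.exponential(1.0 / rates[1], n),
        )
        out.extend(t[t >= t_min].tolist())
    return np.array(out[:n])


# --------------------------------------------------------------------------- #
# extraction and ECDF
# --------------------------------------------------------------------------- #

def test_extract_dwells_hand_counted(stub_ideal):
    ideal = stub_ideal([0, 0, 0, 1, 1, 0, 0], frame_interval=1.0)
    sets = da.extract_dwells([ideal], censor_policy="keep")
    low, high = sets["low"], sets["high"]
    assert sorted(low.durations.tolist()) == [2.0, 3.0]
    assert low.censored.all()  # both low sojourns touch the trace edges
    assert high.durations.tolist() == [2.0]
    assert not high.censored.any()


def test_extract_dwells_drop_policy(stub_ideal):
    ideal = stub_ideal([0, 0, 0, 1, 1, 0, 0], frame_interval=1.0)
    sets = da.extract_dwells([ideal], censor_policy="drop")
    assert sets["low"].durations.size == 0
    assert sets["high"].durations.tolist() == [2.0]


def test_extract_dwells_counts_interior_sojourns(stub_ideal, dna_scheme):
    """Dropped-censor dwell count equals the generator's interior sojourns."""
    rng = np.random.default_rng(4)
    ideals, interior = [], 0
    for _ in range(100):
        sim = syn.simulate_ctmc_trace(dna_scheme, 5.0, 60.0, 0.1, seed=rng)
        ideals.append(stub_ideal(sim.true_class_path, 0.1))
        runs = da._runs(sim.true_class_path)
        interior += max(len(runs) - 2, 0)
    sets = da.extract_dwells(ideals, censor_policy="drop")
    assert len(sets["low"]) + len(sets["high"]) == interior


def test_cumulative_sum_points():
    pts = da.cumulative_sum(np.array([3.0, 1.0, 2.0]))
    assert pts["duration_s"].tolist() == [1.0, 2.0, 3.0]
    assert pts["cdf"].tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])


def test_cumulative_sum_duplicates():
    pts = da.cumulative_sum(np.array([2.0, 2.0]))
    assert pts["cdf"].tolist() == [0.5, 1.0]
    assert pts["duration_s"].iloc[-1] == 2.0


def test_ecdf_within_dkw_band(rng):
    """Empirical CDF of an exponential sample stays inside the 99% DKW band."""
    n = 20_000
    sample = rng.exponential(1.0, n)
    pts = da.cumulative_sum(sample)
    true_cdf = 1.0 - np.exp(-pts["duration_s"].to_numpy())
    eps = np.sqrt(np.log(2.0 / 0.01) / (2.0 * n))
    assert np.max(np.abs(pts["cdf"].to_numpy() - true_cdf)) < eps


def test_apply_dead_time_filters_and_updates_window(stub_ideal):
    ideal = stub_ideal([0, 1, 0, 0, 1, 1, 1, 0, 1, 0], frame_interval=1.0)
    sets = da.extract_dwells([ideal], censor_policy="drop")
    raised = da.apply_dead_time(sets["high"], 2.0)
    assert raised.t_min == 2.0
    assert np.all(raised.durations >= 2.0)
    with pytest.raises(ValueError):
        da.apply_dead_time(sets["high"], 0.5)


# --------------------------------------------------------------------------- #
# mixture MLE
# --------------------------------------------------------------------------- #

def test_single_exponential_mle_is_inverse_mean(rng):
    t = rng.exponential(2.5, 500)
    fit = da.fit_exp_mixture(t, n_components=1)
    assert fit.rates[0] == pytest.approx(1.0 / t.mean(), rel=1e-9)


def test_windowed_likelihood_reduces_to_standard(rng):
    t = rng.exponential(1.0, 200) + 0.05
    rates, amps = np.array([0.8, 0.1]), np.array([0.7, 0.3])
    wide = da.mixture_loglik(t, rates, amps, t_min=1e-14, t_max=1e14)
    plain = da.mixture_loglik(t, rates, amps, t_min=0.0, t_max=np.inf)
    assert wide == pytest.approx(plain, abs=1e-9)


def test_mixture_recovery_at_published_dna_rates(rng):
    """5000 dwells from 0.75 Exp(0.58) + 0.25 Exp(0.036) truncated at 0.1 s:
    rates recovered within 10%, amplitudes within 0.05."""
    rates_true = np.array([0.58, 0.036])
    amps_true = np.array([0.75, 0.25])
    t = draw_truncated_mixture(rng, 5000, rates_true, amps_true, t_min=0.1)
    fit = da.fit_exp_mixture(t, n_components=2, t_min=0.1, t_max=np.inf)
    # primary component (larger amplitude) is the faster one here
    assert fit.primary_index == 0
    assert fit.rates[0] == pytest.approx(0.58, rel=0.10)
    assert fit.rates[1] == pytest.approx(0.036, rel=0.10)
    assert fit.amplitudes[0] == pytest.approx(0.75, abs=0.05)


def test_grid_search_oracle_never_beats_fitter(rng):
    """Coarse (k1, k2) grid with profiled amplitude cannot exceed the MLE."""
    t = draw_truncated_mixture(
        rng, 2000, np.array([0.58, 0.036]), np.array([0.75, 0.25]), t_min=0.1
    )
    fit = da.fit_exp_mixture(t, n_components=2, t_min=0.1, t_max=np.inf)
    best_grid = -np.inf
    for k1 in np.geomspace(0.05, 5.0, 12):
        for k2 in np.geomspace(0.005, 0.5, 12):
            for a in np.linspace(0.05, 0.95, 19):
                ll = da.mixture_loglik(
                    t, np.array([k1, k2]), np.array([a, 1 - a]),
                    t_min=0.1, t_max=np.inf,
                )
                best_grid = max(best_grid, ll)
    assert best_grid <= fit.loglik + 1e-6


def test_mixture_mean_close_to_sample_mean(rng):
    t = rng.exponential(1.5, 1200)
    fit = da.fit_exp_mixture(t, n_components=2, bootstrap_reps=40, rng=1)
    se = 3.0 * t.std() / np.sqrt(t.size)
    assert abs(fit.mixture_mean - t.mean()) < max(se, 3.0 * 0.05 * t.mean())


def test_fit_rejects_too_few_dwells():
    with pytest.raises(ValueError, match="10 uncensored"):
        da.fit_exp_mixture(np.array([1.0] * 9), n_components=1)


def test_fit_output_sorted_by_amplitude_and_deterministic(rng):
    t = draw_truncated_mixture(
        rng, 1500, np.array([1.0, 0.05]), np.array([0.3, 0.7])
    )
    f_a = da.fit_exp_mixture(t, n_components=2)
    f_b = da.fit_exp_mixture(t, n_components=2)
    assert f_a.amplitudes[0] >= f_a.amplitudes[1]
    assert np.array_equal(f_a.rates, f_b.rates)  # deterministic multistart
    # slower component carries the larger amplitude here
    assert f_a.rates[0] < f_a.rates[1]
    assert f_a.primary_rate == f_a.rates[0]


def test_boundary_amplitude_flagged(rng):
    t = rng.exponential(1.0, 800)
    fit = da.fit_exp_mixture(t, n_components=2)
    llr = "effectively_single_exponential" in fit.flags
    # mono-exponential data: either the amplitude pins to the boundary or
    # the two rates collapse; in both cases the extra component is idle
    assert llr or abs(fit.rates[0] - fit.rates[1]) / fit.rates[0] < 0.3 \
        or fit.amplitudes.min() < 0.05


def test_censored_survival_contribution_keeps_longer_dwells(rng):
    """Right-censored dwells pull the fitted rate down relative to dropping
    them (they testify that the sojourn lasted at least that long)."""
    t_obs = rng.exponential(1.0, 400)
    t_cen = np.full(100, 3.0)
    dwells = da.DwellSet(
        label="x",
        durations=np.concatenate([t_obs, t_cen]),
        censored=np.concatenate(
            [np.zeros(400, dtype=bool), np.ones(100, dtype=bool)]
        ),
    )
    fit_keep = da.fit_exp_mixture(dwells, n_components=1)
    fit_drop = da.fit_exp_mixture(t_obs, n_components=1)
    assert fit_keep.rates[0] < fit_drop.rates[0]


# --------------------------------------------------------------------------- #
# model selection
# --------------------------------------------------------------------------- #

def test_identical_fits_give_zero_llr_and_single():
    f1 = da.ExpMixFit(1, np.array([1.0]), np.array([1.0]), -100.0, 0.0,
                      np.inf, 500)
    f2 = da.ExpMixFit(2, np.array([1.0, 1.0]), np.array([0.5, 0.5]), -100.0,
                      0.0, np.inf, 500)
    choice = da.select_model(f1, f2)
    assert choice.llr == 0.0
    assert choice.chosen == 1


def test_mismatched_windows_rejected():
    f1 = da.ExpMixFit(1, np.array([1.0]), np.array([1.0]), -10.0, 0.0,
                      np.inf, 100)
    f2 = da.ExpMixFit(2, np.array([1.0, 2.0]), np.array([0.5, 0.5]), -9.0,
                      0.5, np.inf, 100)
    with pytest.raises(ValueError, match="window"):
        da.select_model(f1, f2)


def test_power_against_strong_mixture(rng):
    """Two-component data at the naked-DNA rate contrast: double model chosen
    in essentially every replicate at n = 500."""
    chosen = []
    for _ in range(40):
        t = draw_truncated_mixture(
            rng, 500, np.array([0.58, 0.036]), np.array([0.75, 0.25])
        )
        f1 = da.fit_exp_mixture(t, 1)
        f2 = da.fit_exp_mixture(t, 2)
        chosen.append(da.select_model(f1, f2).chosen)
    assert np.mean(np.array(chosen) == 2) >= 0.95


def test_bootstrap_mode_agrees_with_chi2_on_obvious_mixture(rng):
    t = draw_truncated_mixture(
        rng, 600, np.array([0.58, 0.036]), np.array([0.75, 0.25])
    )
    dwells = da.DwellSet(label="x", durations=t,
                         censored=np.zeros(t.size, dtype=bool))
    f1 = da.fit_exp_mixture(dwells, 1)
    f2 = da.fit_exp_mixture(dwells, 2)
    choice = da.select_model(f1, f2, mode="bootstrap", dwells=dwells,
                             n_boot=19, rng=5)
    assert choice.chosen == 2
    assert choice.p_value == pytest.approx(1.0 / 20.0)
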
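"""Dwell-time extraction and censored exponential-mixture maximum likelihood.

From idealized traces, consecutive same-class runs become dwell times; the
first and last sojourn of every trace are flagged as censored because their
true length is only bounded below by the observation window.  Dwell sets are
fit with single- or two-component exponential mixtures by maximizing the
window-truncated likelihood

    sum_j log f(t_j) - n log [F(t_max) - F(t_min)],

which accounts for the camera dead time t_min (shorter events are
unobservable) and the finite movie length t_max.  Nested single- vs
double-exponential fits are compared with a log-likelihood-ratio statistic,
either against a chi-square reference (df = 2: one extra rate plus one
amplitude) or by parametric bootstrap under the fitted single-exponential
null, which is the rigorous choice given the boundary non-regularity of
mixture likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "DwellSet",
    "ExpMixFit",
    "ModelChoice",
    "extract_dwells",
    "apply_dead_time",
    "cumulative_sum",
    "fit_exp_mixture",
    "select_model",
]


@dataclass
class DwellSet:
    """Per-class dwell durations with censoring flags and fit window."""

    label: str
    durations: np.ndarray
    censored: np.ndarray
    concentration: float | None = None
    t_min: float = 0.0
    t_max: float = np.inf
    n_traces: int = 0

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.size != self.censored.size:
            raise ValueError("censored flags must align with durations")
        if np.any(self.durations < self.t_min - 1e-12):
            raise ValueError("durations below the dead time t_min")

    @property
    def uncensored(self) -> np.ndarray:
        return self.durations[~self.censored]

    def __len__(self) -> int:
        return self.durations.size


@dataclass
class ExpMixFit:
    """Fitted exponential mixture, components sorted by amplitude descending."""

    n_components: int
    rates: np.ndarray
    amplitudes: np.ndarray
    loglik: float
    t_min: float
    t_max: float
    n: int
    rate_ses: np.ndarray | None = None
    amplitude_ses: np.ndarray | None = None
    lattice_dt: float | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if np.any(self.rates <= 0):
            raise ValueError("rates must be positive")
        if abs(self.amplitudes.sum() - 1.0) > 1e-10:
            raise ValueError("amplitudes must sum to 1")
        if np.any((self.amplitudes < -1e-12) | (self.amplitudes > 1 + 1e-12)):
            raise ValueError("amplitudes must lie in [0, 1]")

    @property
    def primary_index(self) -> int:
        return int(np.argmax(self.amplitudes))

    @property
    def primary_rate(self) -> float:
        return float(self.rates[self.primary_index])

    @property
    def mixture_mean(self) -> float:
        return float(np.sum(self.amplitudes / self.rates))


@dataclass
class ModelChoice:
    chosen: int
    llr: float
    p_value: float
    alpha: float
    mode: str


# --------------------------------------------------------------------------- #
# dwell extraction
# --------------------------------------------------------------------------- #

def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """(class, run_length) for consecutive runs in a label path."""
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate([[0], change, [labels.size]])
    return [
        (int(labels[a]), int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def extract_dwells(
    idealized: list,
    frame_interval: float | None = None,
    censor_policy: str = "drop",
    concentration: float | None = None,
) -> dict[str, DwellSet]:
    """Per-class dwell sets from idealized traces.

    Durations are run length times the frame interval.  The first and last
    sojourn of each trace are censored; ``censor_policy='drop'`` removes
    them, ``'keep'`` retains them flagged as right-censored so the mixture
    fit can use their survival contribution.
    """
    if not idealized:
        raise ValueError("no idealized traces")
    if censor_policy not in ("drop", "keep"):
        raise ValueError("censor_policy must be 'drop' or 'keep'")
    dt = frame_interval
    durations: dict[int, list[float]] = {0: [], 1: []}
    censored: dict[int, list[bool]] = {0: [], 1: []}
    t_max = 0.0
    for ideal in idealized:
        labels = np.asarray(ideal.labels)
        this_dt = dt if dt is not None else ideal.frame_interval
        t_max = max(t_max, labels.size * this_dt)
        runs = _runs(labels)
        for k, (cls, length) in enumerate(runs):
            is_edge = k == 0 or k == len(runs) - 1
            if is_edge and censor_policy == "drop":
                continue
            durations[cls].append(length * this_dt)
            censored[cls].append(is_edge)
    dt_eff = dt if dt is not None else idealized[0].frame_interval
    out = {}
    for cls, name in ((0, "low"), (1, "high")):
        out[name] = DwellSet(
            label=name,
            durations=np.array(durations[cls]),
            censored=np.array(censored[cls], dtype=bool),
            concentration=concentration,
            t_min=dt_eff,
            t_max=t_max,
            n_traces=len(idealized),
        )
    return out


def apply_dead_time(dwells: DwellSet, t_min: float) -> DwellSet:
    """Raise the dead time: drop dwells shorter than ``t_min``.

    Single-frame dwells are dominated by idealization blips (isolated
    misassigned frames), so analyses typically fit only dwells of at least
    two frames, with the truncated likelihood accounting for the discarded
    mass.
    """
    if t_min < dwells.t_min:
        raise ValueError("new dead time must not shrink the window")
    keep = dwells.durations >= t_min - 1e-12
    return DwellSet(
        label=dwells.label,
        durations=dwells.durations[keep],
        censored=dwells.censored[keep],
        concentration=dwells.concentration,
        t_min=t_min,
        t_max=dwells.t_max,
        n_traces=dwells.n_traces,
    )


def cumulative_sum(dwells: DwellSet | np.ndarray) -> pd.DataFrame:
    """Empirical CDF points (sorted durations, i/n), the cumulative-sum plot."""
    durations = dwells.durations if isinstance(dwells, DwellSet) else np.asarray(dwells)
    if durations.size == 0:
        raise ValueError("empty dwell set")
    srt = np.sort(durations)
    return pd.DataFrame(
        {"duration_s": srt, "cdf": np.arange(1, srt.size + 1) / srt.size}
    )


# --------------------------------------------------------------------------- #
# windowed mixture likelihood
# --------------------------------------------------------------------------- #

def _window_mass(rates: np.ndarray, amps: np.ndarray, t_min: float, t_max: float):
    """F(t_max) - F(t_min) for the mixture."""
    lo = np.exp(-rates * t_min)
    hi = np.exp(-rates * t_max) if np.isfinite(t_max) else 0.0
    return float(np.sum(amps * (lo - hi)))


def mixture_loglik(
    t: np.ndarray,
    rates: np.ndarray,
    amps: np.ndarray,
    t_min: float = 0.0,
    t_max: float = np.inf,
    censored: np.ndarray | None = None,
    lattice_dt: float | None = None,
) -> float:
    """Window-truncated mixture log-likelihood.

    Uncensored dwells contribute log f(t); right-censored dwells contribute
    log [S(t) - S(t_max)]; both are normalized by the window probability
    mass F(t_max) - F(t_min).

    ``lattice_dt`` switches to the interval-censored form for dwell times
    quantized to multiples of the frame interval: an observed duration t
    stands for a true duration in [t - dt/2, t + dt/2), so the contribution
    is log [S(t - dt/2) - S(t + dt/2)] with the window shifted accordingly.
    Evaluating a continuous density at lattice points instead would reward
    spurious spike components parked on the first observable point.
    """
    t = np.asarray(t, dtype=float)
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    amps = np.atleast_1d(np.asarray(amps, dtype=float))
    if censored is None:
        censored = np.zeros(t.size, dtype=bool)
    if lattice_dt is not None:
        half = lattice_dt / 2.0
        lo_edge = max(t_min - half, 0.0)
        hi_edge = t_max + half if np.isfinite(t_max) else np.inf
        w = _window_mass(rates, amps, lo_edge, hi_edge)
        if w <= 0:
            return -np.inf
        ll = 0.0
        obs = t[~censored]
        if obs.size:
            lo = np.maximum(obs - half, 0.0)
            mass = np.sum(
                amps[None, :]
                * (np.exp(-rates[None, :] * lo[:, None])
                   - np.exp(-rates[None, :] * (obs[:, None] + half))),
                axis=1,
            )
            if np.any(mass <= 0):
                return -np.inf
            ll += float(np.sum(np.log(mass)))
        cen = t[censored]
        if cen.size:
            s_end = 0.0 if not np.isfinite(hi_edge) else float(
                np.sum(amps * np.exp(-rates * hi_edge))
            )
            surv = np.sum(
                amps[None, :]
                * np.exp(-rates[None, :] * np.maximum(cen - half, 0.0)[:, None]),
                axis=1,
            ) - s_end
            ll += float(np.sum(np.log(np.maximum(surv, 1e-300))))
        return ll - t.size * np.log(w)

    w = _window_mass(rates, amps, t_min, t_max)
    if w <= 0:
        return -np.inf
    ll = 0.0
    obs = t[~censored]
    if obs.size:
        dens = np.sum(
            amps[None, :] * rates[None, :] * np.exp(-rates[None, :] * obs[:, None]),
            axis=1,
        )
        if np.any(dens <= 0):
            return -np.inf
        ll += float(np.sum(np.log(dens)))
    cen = t[censored]
    if cen.size:
        s_tmax = 0.0 if not np.isfinite(t_max) else np.sum(
            amps * np.exp(-rates * t_max)
        )
        surv = np.sum(
            amps[None, :] * np.exp(-rates[None, :] * cen[:, None]), axis=1
        ) - s_tmax
        surv = np.maximum(surv, 1e-300)
        ll += float(np.sum(np.log(surv)))
    return ll - t.size * np.log(w)


def _fit_single(t, censored, t_min, t_max, lattice_dt=None) -> tuple[float, float]:
    """MLE of a single truncated exponential; returns (rate, loglik)."""
    mean = float(np.mean(t[~censored])) if np.any(~censored) else float(np.mean(t))
    if (t_min <= 1e-300 and not np.isfinite(t_max) and not np.any(censored)
            and lattice_dt is None):
        k = 1.0 / mean  # closed-form MLE
        return k, mixture_loglik(t, np.array([k]), np.array([1.0]), t_min, t_max)
    def nll(logk):
        k = np.exp(logk)
        return -mixture_loglik(
            t, np.array([k]), np.array([1.0]), t_min, t_max, censored,
            lattice_dt=lattice_dt,
        )
    k_hi = min(1e8 / mean, _rate_cap(t_min))
    res = optimize.minimize_scalar(
        nll, bounds=(np.log(1e-8 / mean), np.log(k_hi)),
        method="bounded", options={"xatol": 1e-12},
    )
    k = float(np.exp(res.x))
    return k, -float(res.fun)


def _pack2(k1, k2, a1):
    return np.array([np.log(k1), np.log(k2), np.log(a1 / (1 - a1))])


def _unpack2(theta):
    k = np.exp(np.clip(theta[:2], -700, 700))
    a1 = float(expit(theta[2]))
    return k, np.array([a1, 1.0 - a1])


def _rate_cap(t_min: float) -> float:
    """Fastest identifiable rate: components decaying essentially entirely
    below the dead time are likelihood-flat ghosts and are excluded."""
    return 5.0 / t_min if t_min > 0 else np.inf


def _two_component_starts(t, censored, t_min, t_max, lattice_dt=None) -> list[np.ndarray]:
    """Deterministic multistart grid: method-of-moments plus perturbations."""
    k0, _ = _fit_single(t, censored, t_min, t_max, lattice_dt)
    cap = 0.8 * _rate_cap(t_min)
    k0 = min(k0, cap / 2.0) if np.isfinite(cap) else k0
    obs = t[~censored] if np.any(~censored) else t
    med = np.median(obs)
    k_med = min(np.log(2.0) / max(med, 1e-12), cap)
    def clamp(k):
        return min(k, cap) if np.isfinite(cap) else k

    starts = [
        _pack2(clamp(3.0 * k0), k0 / 3.0, 0.7),
        _pack2(clamp(10.0 * k0), k0 / 10.0, 0.75),
        _pack2(clamp(2.0 * k0), k0 / 5.0, 0.5),
        _pack2(clamp(5.0 * k0), k0 / 2.0, 0.5),
        _pack2(clamp(max(k_med, 1.01 * k0)), k0 / 4.0, 0.6),
        # near-degenerate starts guarantee loglik >= single-exponential fit
        _pack2(1.0001 * k0, k0 / 5.0, 0.98),
        _pack2(clamp(5.0 * k0), 1.0001 * k0, 0.02),
    ]
    return starts


def fit_exp_mixture(
    dwells: DwellSet | np.ndarray,
    n_components: int = 2,
    bootstrap_reps: int = 0,
    rng: int | np.random.Generator | None = None,
    t_min: float | None = None,
    t_max: float | None = None,
    lattice_dt: float | None = None,
) -> ExpMixFit:
    """Maximum-likelihood exponential-mixture fit of a dwell set.

    The likelihood is truncated to the observation window [t_min, t_max]
    (defaults taken from the dwell set: one frame interval and the movie
    length).  Two-component fits run from >= 5 deterministic starts
    (method-of-moments plus spread perturbations) and keep the best
    optimum.  Components are reported sorted by amplitude descending, so
    ``primary`` means the larger-amplitude component regardless of rate.
    Standard errors, if requested, come from a nonparametric bootstrap over
    dwells.

    For dwell times quantized to the camera frame grid, pass the frame
    interval as ``lattice_dt`` to use the interval-censored likelihood (see
    :func:`mixture_loglik`); leave it None for continuous-valued durations.
    """
    if isinstance(dwells, DwellSet):
        t = dwells.durations
        censored = dwells.censored
        t_min = dwells.t_min if t_min is None else t_min
        t_max = dwells.t_max if t_max is None else t_max
    else:
        t = np.asarray(dwells, dtype=float)
        censored = np.zeros(t.size, dtype=bool)
        t_min = 0.0 if t_min is None else t_min
        t_max = np.inf if t_max is None else t_max
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if np.sum(~censored) < 10:
        raise ValueError("need at least 10 uncensored dwells")

    flags: list[str] = []
    if n_components == 1:
        k, ll = _fit_single(t, censored, t_min, t_max, lattice_dt)
        rates = np.array([k])
        amps = np.array([1.0])
    else:
        k_cap = _rate_cap(t_min)

        def nll(theta):
            k, a = _unpack2(theta)
            if np.any(k > k_cap):
                return 1e12 * (1.0 + float(np.sum(np.log(k / k_cap).clip(0))))
            return -mixture_loglik(t, k, a, t_min, t_max, censored,
                                   lattice_dt=lattice_dt)

        best = None
        for theta0 in _two_component_starts(t, censored, t_min, t_max, lattice_dt):
            res = optimize.minimize(
                nll, theta0, method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
            )
            if best is None or res.fun < best.fun:
                best = res
        k, a = _unpack2(best.x)
        order = np.argsort(-a)  # amplitude descending
        rates, amps = k[order], a[order]
        ll = -float(best.fun)
        if amps.min() < 0.01:
            flags.append("effectively_single_exponential")

    fit = ExpMixFit(
        n_components=n_components, rates=rates, amplitudes=amps,
        loglik=float(ll), t_min=float(t_min), t_max=float(t_max),
        n=int(t.size), lattice_dt=lattice_dt, flags=flags,
    )
    if bootstrap_reps > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        boot_rates, boot_amps = [], []
        for _ in range(bootstrap_reps):
            idx = gen.integers(0, t.size, t.size)
            bs = DwellSet(
                label="boot", durations=t[idx], censored=censored[idx],
                t_min=t_min, t_max=t_max,
            )
            try:
                bfit = fit_exp_mixture(bs, n_components, lattice_dt=lattice_dt)
            except ValueError:
                continue
            # align bootstrap components to the point fit by rate proximity
            if n_components == 2:
                if np.argmin(np.abs(np.log(bfit.rates[0] / fit.rates))) == 1:
                    bfit_rates = bfit.rates[::-1]
                    bfit_amps = bfit.amplitudes[::-1]
                else:
                    bfit_rates, bfit_amps = bfit.rates, bfit.amplitudes
            else:
                bfit_rates, bfit_amps = bfit.rates, bfit.amplitudes
            boot_rates.append(bfit_rates)
            boot_amps.append(bfit_amps)
        if boot_rates:
            fit.rate_ses = np.std(np.array(boot_rates), axis=0, ddof=1)
            fit.amplitude_ses = np.std(np.array(boot_amps), axis=0, ddof=1)
    return fit


# --------------------------------------------------------------------------- #
# model selection
# --------------------------------------------------------------------------- #

def _sample_truncated_exp(rate, n, t_min, t_max, rng):
    """Inverse-CDF sampling of Exp(rate) conditioned on [t_min, t_max]."""
    u = rng.random(n)
    lo = np.exp(-rate * t_min)
    hi = np.exp(-rate * t_max) if np.isfinite(t_max) else 0.0
    return -np.log(lo - u * (lo - hi)) / rate


def select_model(
    fit1: ExpMixFit,
    fit2: ExpMixFit,
    alpha: float = 0.05,
    mode: str = "chi2",
    dwells: DwellSet | None = None,
    n_boot: int = 200,
    rng: int | np.random.Generator | None = None,
) -> ModelChoice:
    """Single- vs double-exponential selection by log-likelihood ratio.

    Lambda = 2 (logL_2 - logL_1).  ``mode='chi2'`` refers Lambda to
    chi-square with 2 degrees of freedom; ``mode='bootstrap'`` simulates the
    null distribution of Lambda by parametric bootstrap from the fitted
    single exponential (requires ``dwells``).  The double model is chosen
    when the single model is rejected at level ``alpha``.
    """
    if fit1.n_components != 1 or fit2.n_components != 2:
        raise ValueError("fit1 must be the single-, fit2 the double-exponential fit")
    if (abs(fit1.t_min - fit2.t_min) > 1e-12
            or (fit1.t_max != fit2.t_max
                and abs(fit1.t_max - fit2.t_max) > 1e-9)):
        raise ValueError("mismatched fit windows")
    llr = 2.0 * (fit2.loglik - fit1.loglik)
    if llr < -1e-6 * max(1.0, abs(fit1.loglik)):
        raise RuntimeError("double-exponential fit below nested single fit")
    llr = max(llr, 0.0)

    if mode == "chi2":
        p = float(stats.chi2.sf(llr, df=2))
    elif mode == "bootstrap":
        if dwells is None:
            raise ValueError("bootstrap mode needs the dwell set")
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        rate0 = float(fit1.rates[0])
        dt = fit1.lattice_dt
        exceed = 0
        for _ in range(n_boot):
            if dt is not None:
                sim = _sample_truncated_exp(
                    rate0, len(dwells), max(fit1.t_min - dt / 2.0, 0.0),
                    fit1.t_max, gen,
                )
                sim = np.clip(np.round(sim / dt) * dt, fit1.t_min, fit1.t_max)
            else:
                sim = _sample_truncated_exp(
                    rate0, len(dwells), fit1.t_min, fit1.t_max, gen
                )
            bs = DwellSet(
                label="null", durations=sim,
                censored=np.zeros(sim.size, dtype=bool),
                t_min=fit1.t_min, t_max=fit1.t_max,
            )
            b1 = fit_exp_mixture(bs, 1, lattice_dt=dt)
            b2 = fit_exp_mixture(bs, 2, lattice_dt=dt)
            if max(0.0, 2.0 * (b2.loglik - b1.loglik)) >= llr:
                exceed += 1
        p = (1.0 + exceed) / (n_boot + 1.0)
    else:
        raise ValueError("mode must be 'chi2' or 'bootstrap'")

    return ModelChoice(
        chosen=2 if p <= alpha else 1, llr=float(llr), p_value=p,
        alpha=alpha, mode=mode,
    )
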
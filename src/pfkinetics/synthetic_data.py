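"""Generative models for every input the kinetics pipeline consumes.

Three kinds of data are emulated, all on explicit, seed-deterministic
generative models:

* single-molecule intensity time traces (smPIFE- or smFRET-like), produced
  either from a continuous-time Markov chain with aggregated low/high
  observable classes (:func:`simulate_ctmc_trace`) or from an alternating
  renewal process with exponential-mixture dwell laws
  (:func:`simulate_renewal_trace`);
* ensemble titration tables following a Langmuir/Hill isotherm
  (:func:`simulate_titration`);
* fluorescence-recovery-after-photobleaching ratio curves with an
  immobile fraction (:func:`simulate_frap`).

Concentrations are in nM throughout; times in seconds; intensities in
arbitrary fluorescence units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOW, HIGH = "low", "high"

__all__ = [
    "KineticScheme",
    "RenewalSpec",
    "EmissionModel",
    "SimulatedTrace",
    "TitrationSpec",
    "FRAPSpec",
    "gillespie_path",
    "simulate_ctmc_trace",
    "simulate_renewal_trace",
    "simulate_titration",
    "simulate_frap",
    "reb1_dna_scheme",
    "reb1_nucleosome_scheme",
]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass
class KineticScheme:
    """A continuous-time Markov chain with concentration-scaled edges.

    The realized off-diagonal rate for the ordered state pair (i, j) at TF
    concentration ``c`` (nM) is ``base_rates[i, j] * c ** conc_exponent[i, j]``
    with ``conc_exponent`` entries restricted to {0, 1}: 1 marks a bimolecular
    binding edge, 0 a unimolecular (dissociation or structural) edge.  The
    diagonal of the generator is the negative row sum.  Each state maps onto
    one observable class (``"low"`` or ``"high"``); class dwell distributions
    of such aggregated chains are in general multi-exponential.
    """

    state_labels: list[str]
    base_rates: np.ndarray
    conc_exponent: np.ndarray
    class_map: dict[str, str]

    def __post_init__(self) -> None:
        self.base_rates = np.asarray(self.base_rates, dtype=float)
        self.conc_exponent = np.asarray(self.conc_exponent, dtype=int)
        n = len(self.state_labels)
        if self.base_rates.shape != (n, n) or self.conc_exponent.shape != (n, n):
            raise ValueError("rate matrices must be square, one row per state")
        if not np.all(np.isfinite(self.base_rates)):
            raise ValueError("non-finite base rates")
        off = ~np.eye(n, dtype=bool)
        if np.any(self.base_rates[off] < 0):
            raise ValueError("off-diagonal base rates must be nonnegative")
        if not set(np.unique(self.conc_exponent)) <= {0, 1}:
            raise ValueError("conc_exponent entries must be 0 or 1")
        if set(self.class_map) != set(self.state_labels):
            raise ValueError("class_map must assign every state exactly once")
        classes = set(self.class_map.values())
        if not classes <= {LOW, HIGH}:
            raise ValueError(f"classes must be '{LOW}' or '{HIGH}'")
        if classes != {LOW, HIGH}:
            raise ValueError("scheme must populate both observable classes")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def rate_matrix(self, concentration: float) -> np.ndarray:
        """Realized generator Q(c); rows sum to zero."""
        if concentration < 0:
            raise ValueError("concentration must be >= 0")
        q = self.base_rates * np.power(float(concentration), self.conc_exponent)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def class_of(self, state_index: int) -> str:
        return self.class_map[self.state_labels[state_index]]

    @property
    def class_codes(self) -> np.ndarray:
        """0 for low, 1 for high, indexed by state."""
        return np.array(
            [1 if self.class_map[s] == HIGH else 0 for s in self.state_labels]
        )


@dataclass
class RenewalSpec:
    """Alternating low/high sojourns with exponential-mixture dwell laws.

    Each class dwell law is a mixture of at most two exponentials with rates
    ``k_i`` (s^-1) and amplitudes ``a_i`` summing to 1.
    """

    low_rates: tuple[float, ...]
    low_amps: tuple[float, ...]
    high_rates: tuple[float, ...]
    high_amps: tuple[float, ...]

    def __post_init__(self) -> None:
        for rates, amps, name in (
            (self.low_rates, self.low_amps, LOW),
            (self.high_rates, self.high_amps, HIGH),
        ):
            if not 1 <= len(rates) <= 2 or len(rates) != len(amps):
                raise ValueError(f"{name}: need 1 or 2 components with amplitudes")
            if any(k <= 0 for k in rates):
                raise ValueError(f"{name}: rates must be strictly positive")
            if any(a < 0 or a > 1 for a in amps):
                raise ValueError(f"{name}: amplitudes must lie in [0, 1]")
            if abs(sum(amps) - 1.0) > 1e-12:
                raise ValueError(f"{name}: amplitudes must sum to 1")

    def mean_dwell(self, cls: str) -> float:
        rates, amps = (
            (self.low_rates, self.low_amps) if cls == LOW
            else (self.high_rates, self.high_amps)
        )
        return float(sum(a / k for a, k in zip(amps, rates)))


@dataclass
class EmissionModel:
    """Gaussian class emissions: per-class mean and SD in arbitrary units."""

    mean_low: float = 1.0
    mean_high: float = 1.5
    sd_low: float = 0.1
    sd_high: float = 0.1

    def __post_init__(self) -> None:
        if self.sd_low <= 0 or self.sd_high <= 0:
            raise ValueError("emission SDs must be positive")
        if self.mean_low >= self.mean_high:
            raise ValueError("mean_low must be below mean_high")


@dataclass
class SimulatedTrace:
    """A discretized trace together with its ground-truth paths."""

    times: np.ndarray
    signal: np.ndarray
    true_state_path: np.ndarray
    true_class_path: np.ndarray  # 0 = low, 1 = high, per frame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.signal) == len(self.true_state_path)
                == len(self.true_class_path) == n):
            raise ValueError("trace arrays must share one length")
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(np.abs(dt - dt[0]) > 1e-9):
                raise ValueError("time grid must be uniform")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "signal": self.signal,
                "true_class": np.where(self.true_class_path == 1, HIGH, LOW),
            }
        )


@dataclass
class TitrationSpec:
    """Langmuir/Hill titration response model.

    response(c) = f0 + (f1 - f0) * c^n / (s_half^n + c^n) + Gaussian noise.
    ``s_half`` is the half-saturation concentration S_1/2 in nM.
    """

    s_half: float
    concentrations: np.ndarray
    f0: float = 0.0
    f1: float = 1.0
    hill_n: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.s_half <= 0:
            raise ValueError("S_1/2 must be positive")
        if self.hill_n <= 0:
            raise ValueError("Hill exponent must be positive")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    def response(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        cn = np.power(c, self.hill_n)
        return self.f0 + (self.f1 - self.f0) * cn / (self.s_half ** self.hill_n + cn)


@dataclass
class FRAPSpec:
    """Single-exponential recovery with bleach depth and mobile fraction.

    Post-bleach normalized ratio:
    R(t) = (1 - depth) + depth * mobile * (1 - exp(-t ln2 / t_half)),
    with t measured from the bleach event.  ``t_half = tau * ln 2``.
    """

    t_half: float
    depth: float = 0.8
    mobile: float = 0.9
    n_prebleach: int = 2
    noise_sd: float = 0.0
    frame_interval: float = 0.25
    n_postbleach: int = 48

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValueError("half-life must be positive")
        if not 0 < self.depth <= 1:
            raise ValueError("bleach depth must lie in (0, 1]")
        if not 0 <= self.mobile <= 1:
            raise ValueError("mobile fraction must lie in [0, 1]")
        if self.n_prebleach < 2:
            raise ValueError("need at least two pre-bleach frames")

    @property
    def tau(self) -> float:
        return self.t_half / np.log(2.0)

    def recovery(self, t_post: np.ndarray) -> np.ndarray:
        t = np.asarray(t_post, dtype=float)
        return (1.0 - self.depth) + self.depth * self.mobile * (
            1.0 - np.exp(-t * np.log(2.0) / self.t_half)
        )


# --------------------------------------------------------------------------- #
# reference schemes
# --------------------------------------------------------------------------- #

def reb1_dna_scheme(
    k_on: float = 0.032,
    k_off: float = 0.58,
    k_struct_out: float = 0.036 * 25.0 / 75.0,
    k_struct_back: float = 0.022,
) -> KineticScheme:
    """Three-state scheme for a TF on naked DNA probed by PIFE.

    States: U (unbound, low signal), B (bound, high signal), B* (bound in a
    structurally distinct low-signal conformation).  The U->B edge scales
    with concentration (rate ``k_on`` in s^-1 nM^-1); B->U is dissociation;
    B<->B* are the concentration-independent structural transitions.  The
    default structural exit rate scales the secondary dissociation-rate
    constant by the secondary/primary amplitude ratio so the bound-state
    total exit rate stays within 2% of ``k_off``.
    """
    labels = ["U", "B", "B*"]
    base = np.array(
        [
            [0.0, k_on, 0.0],
            [k_off, 0.0, k_struct_out],
            [0.0, k_struct_back, 0.0],
        ]
    )
    exp = np.array([[0, 1, 0], [0, 0, 0], [0, 0, 0]])
    return KineticScheme(labels, base, exp, {"U": LOW, "B": HIGH, "B*": LOW})


def reb1_nucleosome_scheme(
    k_on: float = 0.0006, k_off: float = 0.0044
) -> KineticScheme:
    """Two-state scheme for a TF trapping a partially unwrapped nucleosome.

    The fully wrapped nucleosome is the high-FRET state; the TF-bound,
    partially unwrapped nucleosome is the low-FRET state.  Note the class
    polarity is inverted relative to PIFE: binding *enters* the low class,
    so here the unbound state is ``high`` and the bound state ``low``.
    """
    labels = ["wrapped", "bound"]
    base = np.array([[0.0, k_on], [k_off, 0.0]])
    exp = np.array([[0, 1], [0, 0]])
    return KineticScheme(labels, base, exp, {"wrapped": HIGH, "bound": LOW})


# --------------------------------------------------------------------------- #
# trace simulation
# --------------------------------------------------------------------------- #

def _discretize(
    event_times: np.ndarray,
    states: np.ndarray,
    duration: float,
    dt: float,
    class_codes: np.ndarray,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Map a piecewise-constant state path onto frames.

    ``event_times[k]`` is the entry time of sojourn k in state ``states[k]``;
    the last sojourn extends to ``duration``.  Returns per-frame state and
    class arrays.  ``mode='majority'`` assigns each frame the class occupying
    most of its window (state = the state occupying most of the window);
    ``mode='midpoint'`` samples the path at the frame midpoint.
    """
    n_frames = int(np.floor(duration / dt + 1e-9))
    edges = np.concatenate([event_times, [duration]])
    if mode == "midpoint":
        mids = (np.arange(n_frames) + 0.5) * dt
        idx = np.searchsorted(edges, mids, side="right") - 1
        idx = np.clip(idx, 0, len(states) - 1)
        state_path = states[idx]
        return state_path, class_codes[state_path]
    if mode != "majority":
        raise ValueError("discretization mode must be 'majority' or 'midpoint'")
    n_states = class_codes.size
    occ = np.zeros((n_frames, n_states))
    frame_starts = np.arange(n_frames) * dt
    frame_ends = frame_starts + dt
    for a, b, s in zip(edges[:-1], edges[1:], states):
        if b <= a:
            continue
        lo = max(0, int(np.floor(a / dt)))
        hi = min(n_frames - 1, int(np.floor((b - 1e-12) / dt)))
        if hi < lo:
            continue
        span = np.minimum(frame_ends[lo : hi + 1], b) - np.maximum(
            frame_starts[lo : hi + 1], a
        )
        occ[lo : hi + 1, s] += np.maximum(span, 0.0)
    # majority by class first (the observable), then the dominant state
    class_occ = np.zeros((n_frames, 2))
    for s in range(n_states):
        class_occ[:, class_codes[s]] += occ[:, s]
    class_path = (class_occ[:, 1] > class_occ[:, 0]).astype(int)
    state_path = np.empty(n_frames, dtype=int)
    for cls in (0, 1):
        sel = class_path == cls
        members = np.flatnonzero(class_codes == cls)
        state_path[sel] = members[np.argmax(occ[np.ix_(sel, members)], axis=1)]
    return state_path, class_path


def _emit(
    class_path: np.ndarray, emission: EmissionModel, rng: np.random.Generator
) -> np.ndarray:
    means = np.where(class_path == 1, emission.mean_high, emission.mean_low)
    sds = np.where(class_path == 1, emission.sd_high, emission.sd_low)
    return means + rng.normal(size=class_path.size) * sds


def gillespie_path(
    scheme: KineticScheme,
    concentration: float,
    duration: float,
    rng: np.random.Generator,
    initial_state: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact stochastic simulation of the scheme at one concentration.

    Returns ``(entry_times, states)``: sojourn k occupies state
    ``states[k]`` from ``entry_times[k]`` until the next entry (the last
    sojourn runs to ``duration``).
    """
    q = scheme.rate_matrix(concentration)
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite realized rates")
    n = scheme.n_states
    state = (
        int(rng.choice(n, p=_stationary(q)))
        if initial_state is None else int(initial_state)
    )
    entry_times = [0.0]
    states = [state]
    t = 0.0
    while True:
        exit_rate = -q[state, state]
        if exit_rate <= 0:
            break  # absorbing
        t += rng.exponential(1.0 / exit_rate)
        if t >= duration:
            break
        p = q[state].copy()
        p[state] = 0.0
        state = int(rng.choice(n, p=p / p.sum()))
        entry_times.append(t)
        states.append(state)
    return np.array(entry_times), np.array(states, dtype=int)


def simulate_ctmc_trace(
    scheme: KineticScheme,
    concentration: float,
    duration: float,
    frame_interval: float,
    emission: EmissionModel | None = None,
    seed: int | np.random.Generator = 0,
    bleach_rate: float | None = None,
    initial_state: int | str | None = None,
    discretize: str = "majority",
) -> SimulatedTrace:
    """Exact-event (Gillespie) trajectory of the scheme, discretized to frames.

    Parameters
    ----------
    scheme, concentration
        Kinetic scheme and TF concentration (nM) fixing the generator Q(c).
    duration, frame_interval
        Movie length and camera frame interval, seconds.
    emission
        Gaussian per-class emission model; defaults to 5-SD class separation.
    seed
        Integer seed or a Generator; identical arguments give byte-identical
        traces.
    bleach_rate
        If given, an exponential photobleach time truncates the trace.
    initial_state
        Starting state (index or label); default draws from the stationary
        distribution of Q(c).
    """
    if frame_interval <= 0 or duration <= frame_interval:
        raise ValueError("need duration > frame_interval > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    emission = emission or EmissionModel()

    if isinstance(initial_state, str):
        initial_state = scheme.state_labels.index(initial_state)

    t_end = duration
    if bleach_rate is not None:
        if bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")
        if bleach_rate > 0:
            t_end = min(duration, rng.exponential(1.0 / bleach_rate))

    entry_times, states = gillespie_path(
        scheme, concentration, t_end, rng, initial_state
    )

    obs_duration = np.floor(t_end / frame_interval) * frame_interval
    if obs_duration < frame_interval:
        obs_duration = frame_interval  # keep at least one frame pre-truncation
    state_path, class_path = _discretize(
        np.array(entry_times), np.array(states, dtype=int),
        obs_duration, frame_interval, scheme.class_codes, discretize,
    )
    times = np.arange(state_path.size) * frame_interval
    signal = _emit(class_path, emission, rng)
    meta = {
        "concentration_nM": float(concentration),
        "frame_interval_s": float(frame_interval),
        "duration_s": float(duration),
        "bleach_time_s": None if t_end == duration else float(t_end),
        "emission": vars(emission).copy(),
        "kind": "ctmc",
    }
    return SimulatedTrace(times, signal, state_path, class_path, meta)


def _stationary(q: np.ndarray) -> np.ndarray:
    """Stationary distribution of generator q (null space of q^T)."""
    n = q.shape[0]
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _draw_mixture(
    rates: tuple[float, ...], amps: tuple[float, ...], rng: np.random.Generator
) -> float:
    if len(rates) == 1:
        return rng.exponential(1.0 / rates[0])
    comp = 0 if rng.random() < amps[0] else 1
    return rng.exponential(1.0 / rates[comp])


def simulate_renewal_trace(
    spec: RenewalSpec,
    duration: float,
    frame_interval: float,
    emission: EmissionModel | None = None,
    seed: int | np.random.Generator = 0,
    start_class: str = LOW,
    discretize: str = "majority",
) -> SimulatedTrace:
    """Alternating low/high sojourns drawn from the class mixture laws.

    This generates data distributed exactly as the phenomenological
    dwell-time model fitted downstream (mixture components become mixture
    components), unlike the aggregated CTMC where amplitudes arise from the
    hidden topology.
    """
    if frame_interval <= 0 or duration <= frame_interval:
        raise ValueError("need duration > frame_interval > 0")
    if spec.mean_dwell(LOW) < frame_interval and spec.mean_dwell(HIGH) < frame_interval:
        warnings.warn(
            "frame interval exceeds both mean dwell times; sojourns will be "
            "undersampled", UserWarning, stacklevel=2,
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    emission = emission or EmissionModel()

    cls = 0 if start_class == LOW else 1
    t = 0.0
    entry_times, classes = [0.0], [cls]
    while t < duration:
        if cls == 0:
            t += _draw_mixture(spec.low_rates, spec.low_amps, rng)
        else:
            t += _draw_mixture(spec.high_rates, spec.high_amps, rng)
        cls = 1 - cls
        if t < duration:
            entry_times.append(t)
            classes.append(cls)

    obs_duration = np.floor(duration / frame_interval) * frame_interval
    class_codes = np.array([0, 1])  # identity: state == class here
    state_path, class_path = _discretize(
        np.array(entry_times), np.array(classes, dtype=int),
        obs_duration, frame_interval, class_codes, discretize,
    )
    times = np.arange(state_path.size) * frame_interval
    signal = _emit(class_path, emission, rng)
    meta = {
        "frame_interval_s": float(frame_interval),
        "duration_s": float(duration),
        "emission": vars(emission).copy(),
        "kind": "renewal",
    }
    return SimulatedTrace(times, signal, state_path, class_path, meta)


# --------------------------------------------------------------------------- #
# titration and FRAP simulation
# --------------------------------------------------------------------------- #

def simulate_titration(
    spec: TitrationSpec, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Titration table with columns concentration_nM, response."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    resp = spec.response(spec.concentrations)
    if spec.noise_sd > 0:
        resp = resp + rng.normal(size=resp.size) * spec.noise_sd
    return pd.DataFrame({"concentration_nM": spec.concentrations, "response": resp})


def simulate_frap(
    spec: FRAPSpec,
    seed: int | np.random.Generator = 0,
    unbleached_level: float = 1000.0,
) -> pd.DataFrame:
    """FRAP intensity table: time_s, bleached_mean, unbleached_mean, postbleach.

    Pre-bleach frames sit at negative times; the bleach event defines t = 0
    and the first post-bleach frame is recorded at the frame midpoint
    (t = frame_interval / 2).  The noise SD applies to the bleached/unbleached
    ratio; the unbleached region is held at ``unbleached_level`` so
    normalization and ratio-invariance are exercised downstream.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dt = spec.frame_interval
    t_pre = -dt * np.arange(spec.n_prebleach, 0, -1)
    t_post = dt / 2.0 + dt * np.arange(spec.n_postbleach)
    ratio_pre = np.ones(spec.n_prebleach)
    ratio_post = spec.recovery(t_post)
    ratio = np.concatenate([ratio_pre, ratio_post])
    if spec.noise_sd > 0:
        ratio = ratio + rng.normal(size=ratio.size) * spec.noise_sd
    times = np.concatenate([t_pre, t_post])
    return pd.DataFrame(
        {
            "time_s": times,
            "bleached_mean": ratio * unbleached_level,
            "unbleached_mean": np.full(times.size, unbleached_level),
            "postbleach": np.concatenate(
                [np.zeros(spec.n_prebleach, dtype=int),
                 np.ones(spec.n_postbleach, dtype=int)]
            ),
        }
    )
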
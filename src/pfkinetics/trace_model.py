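"""Two-state hidden-Markov idealization of single-molecule intensity traces.

A trace fluctuating between a low and a high emission level (PIFE low/high,
or FRET proximity-ratio high/low) is fit with a two-hidden-state HMM with
Gaussian emissions by maximum-likelihood Baum-Welch EM, then idealized into
a step function with the Viterbi path.  The state count is fixed at two by
construction of the assay observable, so no model-complexity machinery is
needed; states are always reported ordered so that mu_low < mu_high.

The EM core operates on batches of equal-length traces with independent
per-trace parameters, which is how the pipeline processes a whole
concentration's worth of molecules in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "HMMParams",
    "IdealizedTrace",
    "qc_filter",
    "fit_two_state_hmm",
    "fit_two_state_hmm_batch",
    "forward_loglik",
    "viterbi_idealize",
    "viterbi_idealize_batch",
    "proximity_ratio",
]

_MIN_FRAMES = 10


@dataclass
class Trace:
    """Uniform-grid intensity time series, optionally with an acceptor channel."""

    times: np.ndarray
    signal: np.ndarray
    acceptor: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.acceptor is not None:
            self.acceptor = np.asarray(self.acceptor, dtype=float)
            if self.acceptor.size != self.signal.size:
                raise ValueError("acceptor channel length mismatch")
        if self.times.size != self.signal.size:
            raise ValueError("times/signal length mismatch")
        if self.times.size < _MIN_FRAMES:
            raise ValueError(f"trace shorter than {_MIN_FRAMES} frames")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.signal))):
            raise ValueError("non-finite values in trace")
        dt = np.diff(self.times)
        if np.any(np.abs(dt - dt[0]) > 1e-9 * max(1.0, abs(dt[0]))):
            raise ValueError("non-uniform time grid")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    @classmethod
    def from_simulated(cls, sim, source_id: str = "") -> "Trace":
        return cls(times=sim.times, signal=sim.signal, source_id=source_id)


@dataclass
class HMMParams:
    """Gaussian-emission two-state HMM parameters (state 0 = low, 1 = high)."""

    mu: np.ndarray            # (2,) class means, mu[0] < mu[1]
    sigma: np.ndarray         # (2,) class SDs, > 0
    transition: np.ndarray    # (2, 2) per-frame transition probabilities
    initial: np.ndarray       # (2,)
    loglik: float = np.nan
    converged: bool = True
    n_iter: int = 0
    loglik_history: list = field(default_factory=list)

    def validate(self) -> None:
        if not self.mu[0] < self.mu[1]:
            raise ValueError("states must satisfy mu_low < mu_high")
        if np.any(self.sigma <= 0):
            raise ValueError("emission SDs must be positive")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > 1e-10:
            raise ValueError("initial distribution must sum to 1")


@dataclass
class IdealizedTrace:
    """Viterbi class path (0 = low, 1 = high) tied to its source trace."""

    labels: np.ndarray
    trace: Trace
    params: HMMParams

    @property
    def frame_interval(self) -> float:
        return self.trace.frame_interval

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.trace.times,
                "class": np.where(self.labels == 1, "high", "low"),
            }
        )


def proximity_ratio(trace: Trace) -> Trace:
    """Per-frame uncorrected FRET proximity ratio I_A / (I_A + I_D).

    The idealization observable for two-channel FRET traces; correction
    factors are irrelevant to dwell timing and are not applied.
    """
    if trace.acceptor is None:
        raise ValueError("proximity ratio needs an acceptor channel")
    total = trace.signal + trace.acceptor
    if np.any(total <= 0):
        raise ValueError("nonpositive total intensity")
    return Trace(
        times=trace.times, signal=trace.acceptor / total,
        source_id=trace.source_id,
    )


# --------------------------------------------------------------------------- #
# quality control
# --------------------------------------------------------------------------- #

def estimate_snr(signal: np.ndarray) -> float:
    """Two-level separation over noise: (p90 - p10) / robust noise SD.

    Noise is estimated from lag-1 differences (std(diff)/sqrt(2)), which is
    insensitive to slow two-state switching.
    """
    signal = np.asarray(signal, dtype=float)
    noise = np.std(np.diff(signal)) / np.sqrt(2.0)
    if noise == 0:
        return np.inf
    p10, p90 = np.percentile(signal, [10, 90])
    return float((p90 - p10) / noise)


def qc_filter(
    traces: list[Trace],
    require_second_channel: bool = False,
    min_snr: float | None = None,
    min_frames: int | None = None,
) -> tuple[list[Trace], pd.DataFrame]:
    """Deterministic trace quality filter with per-trace rejection reasons.

    Returns the accepted subset and a report with one row per input trace
    (columns: source_id, accepted, reason, snr, n_frames).  The acceptance
    fraction is stored in ``report.attrs['acceptance_fraction']``.
    """
    if not traces:
        raise ValueError("empty input set")
    rows = []
    accepted: list[Trace] = []
    for i, tr in enumerate(traces):
        snr = estimate_snr(tr.signal)
        reason = ""
        if require_second_channel and tr.acceptor is None:
            reason = "no_second_channel"
        elif min_frames is not None and tr.signal.size < min_frames:
            reason = "too_short"
        elif min_snr is not None and snr < min_snr:
            reason = "low_snr"
        if not reason:
            accepted.append(tr)
        rows.append(
            {
                "source_id": tr.source_id or str(i),
                "accepted": not reason,
                "reason": reason,
                "snr": snr,
                "n_frames": tr.signal.size,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["acceptance_fraction"] = len(accepted) / len(traces)
    return accepted, report


# --------------------------------------------------------------------------- #
# batched forward/backward machinery
# --------------------------------------------------------------------------- #

def _emission_probs(x: np.ndarray, mu: np.ndarray, sig: np.ndarray) -> np.ndarray:
    """Gaussian densities b[n, t, k] for batch signals x (n, T)."""
    z = (x[:, :, None] - mu[:, None, :]) / sig[:, None, :]
    return np.exp(-0.5 * z * z) / (np.sqrt(2.0 * np.pi) * sig[:, None, :])


def _forward(b, a_mat, pi):
    """Scaled forward pass.  Returns alpha (n,T,2), scale c (n,T), loglik (n,)."""
    n, t_len, _ = b.shape
    alpha = np.empty_like(b)
    c = np.empty((n, t_len))
    al = pi * b[:, 0]
    c[:, 0] = al.sum(axis=1)
    alpha[:, 0] = al / c[:, 0, None]
    for t in range(1, t_len):
        al = np.einsum("ni,nij->nj", alpha[:, t - 1], a_mat) * b[:, t]
        c[:, t] = al.sum(axis=1)
        alpha[:, t] = al / c[:, t, None]
    return alpha, c, np.log(c).sum(axis=1)


def _backward(b, a_mat, c):
    n, t_len, _ = b.shape
    beta = np.empty_like(b)
    beta[:, -1] = 1.0
    for t in range(t_len - 2, -1, -1):
        beta[:, t] = np.einsum(
            "nij,nj->ni", a_mat, b[:, t + 1] * beta[:, t + 1]
        ) / c[:, t + 1, None]
    return beta


def _auto_init(x: np.ndarray) -> tuple[np.ndarray, ...]:
    """Percentile-based initialization for batch signals x (n, T)."""
    p10 = np.percentile(x, 10, axis=1)
    p90 = np.percentile(x, 90, axis=1)
    sd = x.std(axis=1)
    if np.any(sd == 0) or np.any(p90 <= p10):
        raise ValueError("degenerate trace: no signal variance")
    mu = np.stack([p10, p90], axis=1)
    sig = np.stack([sd / 2.0, sd / 2.0], axis=1)
    n = x.shape[0]
    a_mat = np.broadcast_to(
        np.array([[0.95, 0.05], [0.05, 0.95]]), (n, 2, 2)
    ).copy()
    pi = np.full((n, 2), 0.5)
    return mu, sig, a_mat, pi


def _em_batch(x, mu, sig, a_mat, pi, tol, max_iter, sigma_floor_frac=1e-4):
    """Baum-Welch on a batch with independent per-trace parameters.

    Returns updated (mu, sig, a_mat, pi, loglik, histories, converged).
    The log-likelihood of each trace is non-decreasing across iterations.
    """
    n, t_len = x.shape
    floor = sigma_floor_frac * (x.max(axis=1) - x.min(axis=1) + 1e-300)
    histories: list[list[float]] = [[] for _ in range(n)]
    prev_ll = np.full(n, -np.inf)
    converged = np.zeros(n, dtype=bool)
    ll = prev_ll
    for it in range(max_iter):
        b = _emission_probs(x, mu, sig)
        alpha, c, ll = _forward(b, a_mat, pi)
        beta = _backward(b, a_mat, c)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)
        xi_sum = _xi_sum(alpha, beta, b, c, a_mat)
        for i in range(n):
            histories[i].append(float(ll[i]))
        done = np.abs(ll - prev_ll) < tol
        converged |= done
        if np.all(done):
            prev_ll = ll
            break
        prev_ll = ll
        # M-step
        pi = gamma[:, 0]
        denom = gamma[:, :-1].sum(axis=1)[:, :, None]
        a_mat = xi_sum / np.maximum(denom, 1e-300)
        a_mat /= a_mat.sum(axis=2, keepdims=True)
        w = gamma.sum(axis=1)
        mu = np.einsum("ntk,nt->nk", gamma, x) / w
        var = np.einsum("ntk,ntk->nk", gamma, (x[:, :, None] - mu[:, None, :]) ** 2) / w
        sig = np.maximum(np.sqrt(var), floor[:, None])
    return mu, sig, a_mat, pi, ll, histories, converged


def _xi_sum(alpha, beta, b, c, a_mat):
    """Sum over t of the pairwise posteriors xi_t(i, j), batched."""
    bb = b[:, 1:] * beta[:, 1:] / c[:, 1:, None]
    return np.einsum("nti,ntj->nij", alpha[:, :-1], bb) * a_mat


def _order_low_high(mu, sig, a_mat, pi):
    """Permute states so mu[:, 0] <= mu[:, 1] in every batch member."""
    swap = mu[:, 0] > mu[:, 1]
    if np.any(swap):
        perm = np.where(swap[:, None], [1, 0], [0, 1])
        idx = np.arange(mu.shape[0])[:, None]
        mu = mu[idx, perm]
        sig = sig[idx, perm]
        pi = pi[idx, perm]
        a_new = a_mat.copy()
        for i in np.flatnonzero(swap):
            a_new[i] = a_mat[i][::-1, ::-1]
        a_mat = a_new
    return mu, sig, a_mat, pi


def fit_two_state_hmm_batch(
    signals: np.ndarray,
    init: HMMParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> list[HMMParams]:
    """Fit independent two-state HMMs to a stack of equal-length traces."""
    x = np.asarray(signals, dtype=float)
    if x.ndim != 2:
        raise ValueError("signals must be a 2-D (n_traces, n_frames) array")
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = x.shape[0]
    if init is None:
        mu, sig, a_mat, pi = _auto_init(x)
    else:
        init.validate()
        mu = np.broadcast_to(init.mu, (n, 2)).astype(float).copy()
        sig = np.broadcast_to(init.sigma, (n, 2)).astype(float).copy()
        a_mat = np.broadcast_to(init.transition, (n, 2, 2)).astype(float).copy()
        pi = np.broadcast_to(init.initial, (n, 2)).astype(float).copy()
    if max_iter == 0:
        b = _emission_probs(x, mu, sig)
        _, _, ll = _forward(b, a_mat, pi)
        return [
            HMMParams(mu[i].copy(), sig[i].copy(), a_mat[i].copy(), pi[i].copy(),
                      loglik=float(ll[i]), converged=True, n_iter=0,
                      loglik_history=[float(ll[i])])
            for i in range(n)
        ]
    mu, sig, a_mat, pi, ll, hist, conv = _em_batch(x, mu, sig, a_mat, pi, tol, max_iter)
    mu, sig, a_mat, pi = _order_low_high(mu, sig, a_mat, pi)
    return [
        HMMParams(mu[i].copy(), sig[i].copy(), a_mat[i].copy(), pi[i].copy(),
                  loglik=float(ll[i]), converged=bool(conv[i]),
                  n_iter=len(hist[i]), loglik_history=hist[i])
        for i in range(n)
    ]


def fit_two_state_hmm(
    trace: Trace,
    init: HMMParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> HMMParams:
    """EM fit of a single trace; see :func:`fit_two_state_hmm_batch`."""
    return fit_two_state_hmm_batch(trace.signal[None, :], init, tol, max_iter)[0]


def forward_loglik(trace: Trace, params: HMMParams) -> float:
    """Scaled-forward log-likelihood of the trace under the given parameters."""
    params.validate()
    b = _emission_probs(
        trace.signal[None, :], params.mu[None, :], params.sigma[None, :]
    )
    if not np.all(np.isfinite(b)):
        raise ValueError("non-finite emission densities")
    _, _, ll = _forward(b, params.transition[None], params.initial[None])
    return float(ll[0])


# --------------------------------------------------------------------------- #
# Viterbi
# --------------------------------------------------------------------------- #

def _viterbi_batch(x, mu, sig, a_mat, pi):
    """Most-probable paths; ties broken toward the previous frame's class."""
    n, t_len = x.shape
    logb = -0.5 * ((x[:, :, None] - mu[:, None, :]) / sig[:, None, :]) ** 2 \
        - np.log(sig[:, None, :]) - 0.5 * np.log(2.0 * np.pi)
    with np.errstate(divide="ignore"):
        log_a = np.log(a_mat)
        log_pi = np.log(pi)
    delta = log_pi + logb[:, 0]
    psi = np.empty((n, t_len, 2), dtype=np.int8)
    for t in range(1, t_len):
        cand = delta[:, :, None] + log_a  # cand[n, i, j]
        best = np.argmax(cand, axis=1)
        # persistence tie-break: when both predecessors score equally for
        # state j, keep the path that was already in state j
        tie = cand[:, 0, :] == cand[:, 1, :]
        best = np.where(tie, np.arange(2)[None, :], best)
        psi[:, t] = best
        delta = np.take_along_axis(cand, best[:, None, :], axis=1)[:, 0, :] \
            + logb[:, t]
    paths = np.empty((n, t_len), dtype=np.int8)
    paths[:, -1] = np.argmax(delta, axis=1)
    logp = np.max(delta, axis=1)
    for t in range(t_len - 2, -1, -1):
        paths[:, t] = np.take_along_axis(
            psi[:, t + 1], paths[:, t + 1][:, None].astype(np.intp), axis=1
        )[:, 0]
    return paths, logp


def viterbi_path_logprob(trace: Trace, params: HMMParams) -> float:
    """Joint log-probability of the Viterbi path and the observations."""
    params.validate()
    _, logp = _viterbi_batch(
        trace.signal[None, :], params.mu[None, :], params.sigma[None, :],
        params.transition[None], params.initial[None],
    )
    return float(logp[0])


def viterbi_idealize(trace: Trace, params: HMMParams) -> IdealizedTrace:
    """Idealize one trace into its most probable low/high step function."""
    params.validate()
    paths, _ = _viterbi_batch(
        trace.signal[None, :], params.mu[None, :], params.sigma[None, :],
        params.transition[None], params.initial[None],
    )
    return IdealizedTrace(labels=paths[0].astype(int), trace=trace, params=params)


def viterbi_idealize_batch(
    traces: list[Trace], params_list: list[HMMParams]
) -> list[IdealizedTrace]:
    """Idealize a stack of equal-length traces in one vectorized pass."""
    if len(traces) != len(params_list):
        raise ValueError("one parameter set per trace required")
    x = np.stack([tr.signal for tr in traces])
    mu = np.stack([p.mu for p in params_list])
    sig = np.stack([p.sigma for p in params_list])
    a_mat = np.stack([p.transition for p in params_list])
    pi = np.stack([p.initial for p in params_list])
    paths, _ = _viterbi_batch(x, mu, sig, a_mat, pi)
    return [
        IdealizedTrace(labels=paths[i].astype(int), trace=traces[i],
                       params=params_list[i])
        for i in range(len(traces))
    ]
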
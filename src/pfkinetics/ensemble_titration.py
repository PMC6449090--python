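"""Ensemble titration fitting and (Ratio)_A FRET efficiency.

Titration responses (EMSA fraction bound, ensemble FRET efficiency, or
normalized PIFE fold) are fit to the binding isotherm

    f(c) = f0 + (f1 - f0) * c^n / (S_1/2^n + c^n)

for the half-saturation concentration S_1/2 (nM).  The Hill exponent n is
fixed at 1 by default.  Ensemble FRET efficiencies are computed from
acceptor-band intensities by the (Ratio)_A method: sensitized acceptor
emission under donor excitation normalized by directly excited acceptor
emission, corrected with extinction-coefficient ratios and the
donor-labeling fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IsothermFit",
    "fit_isotherm",
    "ratioA_efficiency",
    "ratioA_forward",
    "pife_enhancement",
]

# Placeholder Cy3/Cy5 correction ratios for 510/610 nm excitation; real
# experiments must supply instrument-specific values.  Results computed with
# these defaults are flagged.
DEFAULT_EPS_A_RATIO = 0.08   # epsilon_A(510) / epsilon_A(610)
DEFAULT_EPS_DA_RATIO = 2.0   # epsilon_D(510) / epsilon_A(610)


@dataclass
class IsothermFit:
    s_half: float
    s_half_se: float
    f0: float
    f1: float
    hill_n: float
    residual_rms: float
    converged: bool = True
    warnings: list = field(default_factory=list)


def _isotherm(c, s_half, f0, f1, n):
    cn = np.power(np.maximum(c, 0.0), n)
    return f0 + (f1 - f0) * cn / (s_half ** n + cn)


def fit_isotherm(
    concentrations: np.ndarray,
    responses: np.ndarray,
    sds: np.ndarray | None = None,
    fix_n: float | None = 1.0,
) -> IsothermFit:
    """Nonlinear least-squares isotherm fit with deterministic multistart.

    ``fix_n=1.0`` (default) fits a simple Langmuir isotherm; ``fix_n=None``
    frees the Hill exponent.  S_1/2 starts are log-spaced across the
    concentration range, and the fit is performed on concentrations
    normalized by their maximum so the estimate is exactly equivariant
    under rescaling of the concentration axis.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.size != y.size:
        raise ValueError("concentration/response length mismatch")
    if c.size < 4:
        raise ValueError("need at least 4 titration points")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    pos = c[c > 0]
    if pos.size < 2 or pos.max() / pos.min() < 10.0:
        warnings.warn("titration spans less than one decade", UserWarning,
                      stacklevel=2)

    warns: list[str] = []
    span = y.max() - y.min()
    scale = max(abs(y).max(), 1.0)
    if span < 1e-9 * scale:
        warns.append("no binding signal")
        return IsothermFit(
            s_half=np.nan, s_half_se=np.nan, f0=float(y.mean()),
            f1=float(y.mean()), hill_n=fix_n or np.nan,
            residual_rms=float(np.std(y)), converged=False, warnings=warns,
        )
    order = np.argsort(c)
    rho = np.corrcoef(c[order], y[order])[0, 1]
    if abs(rho) < 0.3:
        warns.append("no monotonic trend")

    c_ref = c.max()
    cs = c / c_ref
    sigma = None if sds is None else np.asarray(sds, dtype=float)
    f0_guess, f1_guess = y[order][0], y[order][-1]
    guesses = np.geomspace(max(cs[cs > 0].min(), 1e-4), 10.0, 7)

    best = None
    for s_guess in guesses:
        if fix_n is None:
            model = lambda cc, s, f0, f1, n: _isotherm(cc, s, f0, f1, n)
            p0 = [s_guess, f0_guess, f1_guess, 1.0]
            bounds = ([1e-12, -np.inf, -np.inf, 1e-3],
                      [np.inf, np.inf, np.inf, 10.0])
        else:
            model = lambda cc, s, f0, f1: _isotherm(cc, s, f0, f1, fix_n)
            p0 = [s_guess, f0_guess, f1_guess]
            bounds = ([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
        try:
            popt, pcov = curve_fit(
                model, cs, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((model(cs, *popt) - y) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        warns.append("non-convergence")
        return IsothermFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                           converged=False, warnings=warns)
    ssr, popt, pcov = best
    perr = np.sqrt(np.diag(pcov))
    n_fit = popt[3] if fix_n is None else fix_n
    return IsothermFit(
        s_half=float(popt[0] * c_ref),
        s_half_se=float(perr[0] * c_ref),
        f0=float(popt[1]), f1=float(popt[2]), hill_n=float(n_fit),
        residual_rms=float(np.sqrt(ssr / c.size)),
        converged=True, warnings=warns,
    )


def ratioA_efficiency(
    f_ad: float,
    f_aa: float,
    eps_a_ratio: float = DEFAULT_EPS_A_RATIO,
    eps_da_ratio: float = DEFAULT_EPS_DA_RATIO,
    d_plus: float = 1.0,
) -> float:
    """FRET efficiency from acceptor-band intensities, (Ratio)_A method.

    (Ratio)_A = F_AD / F_AA, the acceptor emission under donor excitation
    (donor bleed-through already subtracted) over the directly excited
    acceptor emission.  Then

        E = [(Ratio)_A - eps_A(Dex)/eps_A(Aex)] / (d_plus * eps_D(Dex)/eps_A(Aex))

    where ``d_plus`` is the fraction of acceptor complexes that carry a
    donor.  Values outside [-0.05, 1.05] are clamped to [0, 1] with a
    warning.
    """
    if f_aa == 0:
        raise ValueError("direct acceptor emission F_AA must be nonzero")
    if f_ad < 0 or f_aa < 0:
        raise ValueError("intensities must be >= 0")
    if eps_a_ratio <= 0 or eps_da_ratio <= 0:
        raise ValueError("extinction-coefficient ratios must be positive")
    if not 0 < d_plus <= 1:
        raise ValueError("d_plus must lie in (0, 1]")
    ratio_a = f_ad / f_aa
    e = (ratio_a - eps_a_ratio) / (d_plus * eps_da_ratio)
    if e < -0.05 or e > 1.05:
        warnings.warn(
            f"(Ratio)_A efficiency {e:.3f} outside [-0.05, 1.05]; clamped",
            UserWarning, stacklevel=2,
        )
        e = float(np.clip(e, 0.0, 1.0))
    return float(e)


def ratioA_forward(
    e: float,
    f_aa: float,
    eps_a_ratio: float = DEFAULT_EPS_A_RATIO,
    eps_da_ratio: float = DEFAULT_EPS_DA_RATIO,
    d_plus: float = 1.0,
) -> float:
    """Forward model: sensitized-emission intensity F_AD for a given E."""
    return f_aa * (eps_a_ratio + e * d_plus * eps_da_ratio)


def pife_enhancement(donor_intensity_at_c: float, donor_intensity_at_zero: float) -> float:
    """Fluorescence-enhancement fold I(c) / I(0); baseline fold is 1."""
    if donor_intensity_at_zero <= 0 or donor_intensity_at_c <= 0:
        raise ValueError("intensities must be positive")
    return float(donor_intensity_at_c / donor_intensity_at_zero)
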
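"""Concentration-series rate extraction and the compensation report.

Per-concentration dwell-time fits become rate constants in two ways:

* the concentration-dependent component of the unbound-class exit rate is
  regressed on TF concentration; the slope of the weighted linear fit is
  the bimolecular binding rate constant k_on (s^-1 nM^-1);
* the bound-class exit rates are tested for concentration independence and,
  if independent, pooled by inverse-variance weighting into the
  dissociation rate constant k_off (s^-1).

The apparent dissociation constant is K_D = k_off / k_on.  Comparing DNA
with nucleosome substrates yields the fold reductions in k_on and k_off
whose near-equality is the dissociation-rate compensation signature, and
the single-molecule relative affinity K_D(nuc)/K_D(DNA) is checked against
the ratio of ensemble half-saturation points S_1/2, which cancels the
surface-tethering bias on absolute on-rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ConcentrationSeries",
    "RateFit",
    "CompensationReport",
    "fit_binding_rate",
    "test_concentration_independence",
    "apparent_kd",
    "compensation_report",
    "choose_binding_component",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (headline-fold convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1))


@dataclass
class ConcentrationSeries:
    """Per-concentration rates with uncertainties for one kinetic branch."""

    concentrations: np.ndarray
    rates: np.ndarray
    ses: np.ndarray
    amplitudes: np.ndarray | None = None
    label: str = ""
    substrate: str = ""
    factor: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        if not (self.concentrations.size == self.rates.size == self.ses.size):
            raise ValueError("series arrays must share one length")
        if np.any(self.ses <= 0):
            raise ValueError("rate SEs must be positive")

    def require_multiple_concentrations(self) -> None:
        if np.unique(self.concentrations).size < 2:
            raise ValueError("need >= 2 distinct concentrations")


@dataclass
class RateFit:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    mode: str


def fit_binding_rate(
    series: ConcentrationSeries, through_origin: bool = False
) -> RateFit:
    """Weighted least-squares line through the rate-vs-concentration series.

    Weights are 1/SE^2; the slope is the binding rate constant k_on in
    s^-1 nM^-1.  The default free intercept absorbs any residual
    concentration-independent low-to-high process.
    """
    series.require_multiple_concentrations()
    w = 1.0 / series.ses ** 2
    x = series.concentrations
    exog = x[:, None] if through_origin else sm.add_constant(x)
    res = sm.WLS(series.rates, exog, weights=w).fit()
    # known-variance covariance (X' W X)^-1: the weights are true inverse
    # variances, so parameter errors must not be rescaled by the residuals
    bse = np.sqrt(np.diag(res.normalized_cov_params))
    if through_origin:
        slope, slope_se = res.params[0], bse[0]
        intercept, intercept_se = 0.0, 0.0
    else:
        intercept, slope = res.params
        intercept_se, slope_se = bse
    tss = float(np.sum(w * (series.rates - np.average(series.rates, weights=w)) ** 2))
    r2 = 1.0 - float(res.ssr) / tss if tss > 0 else 1.0
    return RateFit(
        slope=float(slope), slope_se=float(slope_se),
        intercept=float(intercept), intercept_se=float(intercept_se),
        r_squared=r2,
        mode="through-origin" if through_origin else "free-intercept",
    )


def test_concentration_independence(
    series: ConcentrationSeries, alpha: float = 0.05
) -> dict:
    """Slope-vs-zero z-test; pooled inverse-variance mean when independent.

    Returns a dict with ``verdict`` ("independent"/"dependent"), the pooled
    rate and SE (reported regardless of verdict), and the slope test detail.
    """
    series.require_multiple_concentrations()
    fit = fit_binding_rate(series)
    z = fit.slope / fit.slope_se if fit.slope_se > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(z)))
    w = 1.0 / series.ses ** 2
    pooled = float(np.sum(w * series.rates) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    return {
        "verdict": "independent" if p > alpha else "dependent",
        "pooled_rate": pooled,
        "pooled_se": pooled_se,
        "slope": fit.slope,
        "slope_se": fit.slope_se,
        "z": float(z),
        "p_value": p,
        "alpha": alpha,
    }


def apparent_kd(
    k_on: float, k_off: float, se_on: float = 0.0, se_off: float = 0.0
) -> tuple[float, float]:
    """K_D = k_off / k_on in nM, with first-order error propagation."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rate constants must be positive")
    kd = k_off / k_on
    se = kd * np.hypot(se_off / k_off, se_on / k_on)
    return float(kd), float(se)


def choose_binding_component(table: pd.DataFrame) -> tuple[int, float]:
    """Pick the mixture component whose rate tracks TF concentration.

    ``table`` has one row per (concentration, component_rank) with columns
    concentration, rank (0 = fastest rate at that concentration), rate.
    Returns the rank with the highest Pearson correlation between rate and
    concentration, together with that correlation.  The other component is
    interpreted as a concentration-independent structural transition.
    """
    best_rank, best_r = -1, -np.inf
    for rank, grp in table.groupby("rank"):
        if grp["concentration"].nunique() < 2:
            continue
        c = grp["concentration"].to_numpy(dtype=float)
        k = grp["rate"].to_numpy(dtype=float)
        sc, sk = c.std(), k.std()
        # a rate series with zero spread cannot track concentration
        r = 0.0 if sc == 0 or sk == 0 else float(
            np.mean((c - c.mean()) * (k - k.mean())) / (sc * sk)
        )
        if r > best_r:
            best_rank, best_r = int(rank), float(r)
    if best_rank < 0:
        raise ValueError("no component spans multiple concentrations")
    return best_rank, best_r


@dataclass
class CompensationReport:
    """DNA-vs-nucleosome kinetic comparison (the summary-table view)."""

    factor: str
    k_on_dna: float
    k_on_nuc: float
    k_off_dna: float
    k_off_nuc: float
    k_on_dna_se: float = 0.0
    k_on_nuc_se: float = 0.0
    k_off_dna_se: float = 0.0
    k_off_nuc_se: float = 0.0
    s12_dna: float | None = None
    s12_nuc: float | None = None
    derived: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rates = [self.k_on_dna, self.k_on_nuc, self.k_off_dna, self.k_off_nuc]
        if any(r <= 0 for r in rates):
            raise ValueError("all rate constants must be positive")
        kd_dna, kd_dna_se = apparent_kd(
            self.k_on_dna, self.k_off_dna, self.k_on_dna_se, self.k_off_dna_se
        )
        kd_nuc, kd_nuc_se = apparent_kd(
            self.k_on_nuc, self.k_off_nuc, self.k_on_nuc_se, self.k_off_nuc_se
        )
        d = {
            "k_on_fold": self.k_on_dna / self.k_on_nuc,
            "k_off_fold": self.k_off_dna / self.k_off_nuc,
            "kd_dna_nM": kd_dna,
            "kd_dna_se_nM": kd_dna_se,
            "kd_nuc_nM": kd_nuc,
            "kd_nuc_se_nM": kd_nuc_se,
            "sm_relative_affinity": kd_nuc / kd_dna,
        }
        if self.s12_dna is not None and self.s12_nuc is not None:
            if self.s12_dna <= 0 or self.s12_nuc <= 0:
                raise ValueError("S_1/2 values must be positive")
            d["ensemble_relative_affinity"] = self.s12_nuc / self.s12_dna
            d["agreement_ratio"] = (
                d["sm_relative_affinity"] / d["ensemble_relative_affinity"]
            )
        self.derived = d

    def to_dict(self) -> dict:
        out = {
            "factor": self.factor,
            "k_on_dna": self.k_on_dna, "k_on_nuc": self.k_on_nuc,
            "k_off_dna": self.k_off_dna, "k_off_nuc": self.k_off_nuc,
        }
        out.update(self.derived)
        return out

    def to_table(self) -> pd.DataFrame:
        """Human-readable summary; folds rounded to 2 significant figures."""
        d = self.derived
        rows = [
            {
                "factor": self.factor, "substrate": "DNA",
                "k_on_s-1nM-1": self.k_on_dna, "k_off_s-1": self.k_off_dna,
                "KD_nM": d["kd_dna_nM"],
            },
            {
                "factor": self.factor, "substrate": "nucleosome",
                "k_on_s-1nM-1": self.k_on_nuc, "k_off_s-1": self.k_off_nuc,
                "KD_nM": d["kd_nuc_nM"],
            },
        ]
        df = pd.DataFrame(rows)
        df.attrs["k_on_fold"] = round_sig(d["k_on_fold"])
        df.attrs["k_off_fold"] = round_sig(d["k_off_fold"])
        return df


def compensation_report(
    dna: dict,
    nuc: dict,
    ensemble: dict | None = None,
    factor: str = "",
) -> CompensationReport:
    """Build the compensation report from per-substrate rate constants.

    ``dna``/``nuc`` map ``k_on``/``k_off`` to either a value or a
    (value, se) pair; ``ensemble`` optionally supplies ``s12_dna`` and
    ``s12_nuc`` (nM) for the single-molecule vs ensemble affinity check.
    """
    def val_se(d, key):
        if key not in d:
            raise ValueError(f"missing rate constant '{key}'")
        v = d[key]
        return (float(v[0]), float(v[1])) if np.iterable(v) else (float(v), 0.0)

    k_on_dna, se_on_dna = val_se(dna, "k_on")
    k_off_dna, se_off_dna = val_se(dna, "k_off")
    k_on_nuc, se_on_nuc = val_se(nuc, "k_on")
    k_off_nuc, se_off_nuc = val_se(nuc, "k_off")
    ensemble = ensemble or {}
    return CompensationReport(
        factor=factor,
        k_on_dna=k_on_dna, k_on_nuc=k_on_nuc,
        k_off_dna=k_off_dna, k_off_nuc=k_off_nuc,
        k_on_dna_se=se_on_dna, k_on_nuc_se=se_on_nuc,
        k_off_dna_se=se_off_dna, k_off_nuc_se=se_off_nuc,
        s12_dna=ensemble.get("s12_dna"), s12_nuc=ensemble.get("s12_nuc"),
    )
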
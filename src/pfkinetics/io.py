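"""Trace file I/O, pipeline configuration, and the end-to-end driver.

Traces travel as TSV (columns ``time_s``, ``signal``, optional ``acceptor``
and ``true_class``) with a JSON sidecar carrying metadata such as the TF
concentration and the generator seed.  ``run_pipeline`` executes the whole
analysis — simulate or read traces, quality-filter, idealize with the
two-state HMM, extract dwell times, fit exponential mixtures with model
selection, assemble concentration series, and extract k_on / k_off / K_D —
deterministically for a given seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dwell_analysis as da
from . import kinetics as kin
from . import synthetic_data as syn
from . import trace_model as tm

__all__ = [
    "PipelineConfig",
    "read_trace",
    "read_traces",
    "write_trace",
    "run_pipeline",
]


# --------------------------------------------------------------------------- #
# trace I/O
# --------------------------------------------------------------------------- #

def write_trace(trace, path: str | Path, meta: dict | None = None) -> None:
    """Write a trace TSV plus a JSON metadata sidecar (`<path>.json`)."""
    path = Path(path)
    if isinstance(trace, syn.SimulatedTrace):
        df = trace.to_frame()
        meta = {**trace.meta, **(meta or {})}
    else:
        df = pd.DataFrame({"time_s": trace.times, "signal": trace.signal})
        if trace.acceptor is not None:
            df["acceptor"] = trace.acceptor
    df.to_csv(path, sep="\t", index=False)
    if meta is not None:
        with open(f"{path}.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True, default=str)


def read_trace(path: str | Path) -> tuple[tm.Trace, dict]:
    """Read one trace TSV; validates the schema and the uniform time grid.

    Malformed rows and grid gaps are reported with their line numbers
    (1-based, header included).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns or "signal" not in df.columns:
        raise ValueError(f"{path}: missing required columns time_s/signal")
    for col in ("time_s", "signal"):
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if bad.size:
            raise ValueError(
                f"{path}: malformed value in column '{col}' at line {bad[0] + 2}"
            )
    t = df["time_s"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        off = np.flatnonzero(np.abs(dt - dt[0]) > 1e-9 * max(1.0, abs(dt[0])))
        if off.size:
            raise ValueError(
                f"{path}: non-uniform time grid at line {off[0] + 3}"
            )
    acceptor = df["acceptor"].to_numpy(dtype=float) if "acceptor" in df.columns else None
    trace = tm.Trace(
        times=t, signal=df["signal"].to_numpy(dtype=float),
        acceptor=acceptor, source_id=path.stem,
    )
    sidecar = Path(f"{path}.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return trace, meta


def read_traces(path: str | Path) -> list[tuple[tm.Trace, dict]]:
    """Read a trace file or every ``*.tsv`` in a directory, ordered by name."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.tsv"))
        if not files:
            raise FileNotFoundError(f"no .tsv traces under {path}")
        return [read_trace(f) for f in files]
    return [read_trace(path)]


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

@dataclass
class PipelineConfig:
    """Everything the end-to-end driver needs, serializable to YAML.

    With ``input_dir`` unset, traces are simulated from the three-state
    binding scheme below; otherwise they are read from disk and grouped by
    the ``concentration_nM`` field of their sidecars.
    """

    # synthetic generation block
    concentrations: list = field(default_factory=lambda: [2.0, 5.0, 10.0, 15.0])
    n_traces: int = 130
    duration_s: float = 300.0
    frame_interval_s: float = 0.1
    k_on: float = 0.032
    k_off: float = 0.58
    k_struct_out: float = 0.036 * 25.0 / 75.0
    k_struct_back: float = 0.022
    emission_mean_low: float = 1.0
    emission_mean_high: float = 1.5
    emission_sd: float = 0.1
    input_dir: str | None = None
    # trace QC / HMM
    min_snr: float | None = None
    hmm_tol: float = 1e-4
    hmm_max_iter: int = 200
    # dwell analysis
    censor_policy: str = "drop"
    dead_time_frames: int = 2
    selection_mode: str = "chi2"
    alpha: float = 0.05
    unbound_class: str = "low"
    # kinetics
    kon_through_origin: bool = False
    seed: int = 0
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------- #
# pipeline
# --------------------------------------------------------------------------- #

def _simulate_block(cfg: PipelineConfig, seed: int) -> dict[float, list[tm.Trace]]:
    scheme = syn.reb1_dna_scheme(
        cfg.k_on, cfg.k_off, cfg.k_struct_out, cfg.k_struct_back
    )
    emission = syn.EmissionModel(
        mean_low=cfg.emission_mean_low, mean_high=cfg.emission_mean_high,
        sd_low=cfg.emission_sd, sd_high=cfg.emission_sd,
    )
    by_conc: dict[float, list[tm.Trace]] = {}
    root = np.random.SeedSequence(seed)
    for conc, ss in zip(cfg.concentrations, root.spawn(len(cfg.concentrations))):
        rng = np.random.default_rng(ss)
        traces = []
        for j in range(cfg.n_traces):
            sim = syn.simulate_ctmc_trace(
                scheme, conc, cfg.duration_s, cfg.frame_interval_s,
                emission=emission, seed=rng,
            )
            traces.append(tm.Trace.from_simulated(sim, source_id=f"c{conc}_t{j}"))
        by_conc[float(conc)] = traces
    return by_conc


def _read_block(cfg: PipelineConfig) -> dict[float, list[tm.Trace]]:
    by_conc: dict[float, list[tm.Trace]] = {}
    for trace, meta in read_traces(cfg.input_dir):
        conc = meta.get("concentration_nM")
        if conc is None:
            raise ValueError(
                f"trace {trace.source_id}: sidecar lacks concentration_nM"
            )
        by_conc.setdefault(float(conc), []).append(trace)
    return by_conc


def _class_series(results, cls):
    """Assemble (concentration, rank, rate, amp, se) rows for one class.

    rank 0 is the faster, rank 1 the slower component at each concentration.
    A single-component fit feeds both candidate ranks so every candidate
    series spans all concentrations even when the chosen component count
    varies across them.
    """
    rows = []
    for conc, res in results.items():
        fit = res[f"{cls}_fit"]
        n_eff = res[f"{cls}_n"]
        order = np.argsort(-fit.rates)
        for rank in (0, 1):
            i = order[rank] if len(order) == 2 else order[0]
            amp = float(fit.amplitudes[i])
            # asymptotic SE of an exponential-rate MLE on a*n events
            se = float(fit.rates[i] / np.sqrt(max(amp * n_eff, 1.0)))
            rows.append(
                {
                    "concentration": conc, "rank": rank,
                    "rate": float(fit.rates[i]), "amplitude": amp, "se": se,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, seed: int | None = None) -> dict:
    """Execute the full kinetics analysis; deterministic for a given seed.

    Returns the report dict (also written to ``out_dir`` as JSON and TSV
    when configured): per-concentration dwell counts and mixture fits, the
    binding-rate line fit (k_on), the pooled dissociation rate (k_off), and
    the apparent K_D.
    """
    seed = cfg.seed if seed is None else seed
    by_conc = _read_block(cfg) if cfg.input_dir else _simulate_block(cfg, seed)
    if len(by_conc) < 2:
        raise RuntimeError("pipeline stage 'input': need >= 2 concentrations")

    results: dict[float, dict] = {}
    log: list[str] = [f"seed={seed} config={cfg.digest()}"]
    for conc in sorted(by_conc):
        traces = by_conc[conc]
        accepted, report = tm.qc_filter(traces, min_snr=cfg.min_snr)
        if not accepted:
            raise RuntimeError(f"pipeline stage 'qc' ({conc} nM): no traces pass")
        params = tm.fit_two_state_hmm_batch(
            np.stack([tr.signal for tr in accepted]),
            tol=cfg.hmm_tol, max_iter=cfg.hmm_max_iter,
        )
        ideals = tm.viterbi_idealize_batch(accepted, params)
        dwells = da.extract_dwells(
            ideals, censor_policy=cfg.censor_policy, concentration=conc
        )
        res = {
            "n_traces": len(traces),
            "n_accepted": len(accepted),
            "acceptance_fraction": report.attrs["acceptance_fraction"],
        }
        for cls in ("low", "high"):
            lattice_dt = dwells[cls].t_min  # frame interval
            dset = da.apply_dead_time(
                dwells[cls], cfg.dead_time_frames * lattice_dt
            )
            if len(dset.uncensored) < 10:
                raise RuntimeError(
                    f"pipeline stage 'dwells' ({conc} nM, {cls}): too few dwells"
                )
            f1 = da.fit_exp_mixture(dset, 1, lattice_dt=lattice_dt)
            f2 = da.fit_exp_mixture(dset, 2, lattice_dt=lattice_dt)
            choice = da.select_model(
                f1, f2, alpha=cfg.alpha, mode=cfg.selection_mode,
                dwells=dset, rng=seed,
            )
            res[f"{cls}_fit"] = f2 if choice.chosen == 2 else f1
            res[f"{cls}_choice"] = choice
            res[f"{cls}_n"] = len(dset.uncensored)
        results[conc] = res
        log.append(
            f"{conc} nM: {res['n_accepted']}/{res['n_traces']} traces, "
            f"low n={res['low_n']} ({res['low_choice'].chosen} comp), "
            f"high n={res['high_n']} ({res['high_choice'].chosen} comp)"
        )

    unbound, bound = (
        ("low", "high") if cfg.unbound_class == "low" else ("high", "low")
    )
    concs = sorted(results)

    # binding branch: the concentration-correlated component of the unbound class
    unb = _class_series(results, unbound)
    rank_on, corr = kin.choose_binding_component(unb)
    on_rows = unb[unb["rank"] == rank_on].sort_values("concentration")
    on_series = kin.ConcentrationSeries(
        concentrations=on_rows["concentration"].to_numpy(),
        rates=on_rows["rate"].to_numpy(),
        ses=on_rows["se"].to_numpy(),
        amplitudes=on_rows["amplitude"].to_numpy(),
        label=f"{unbound}-exit (binding)",
    )
    kon_fit = kin.fit_binding_rate(on_series, through_origin=cfg.kon_through_origin)

    # dissociation branch: primary (largest-amplitude) bound-class component
    off_rates, off_ses = [], []
    for conc in concs:
        fit = results[conc][f"{bound}_fit"]
        i = fit.primary_index
        n_eff = results[conc][f"{bound}_n"] * float(fit.amplitudes[i])
        off_rates.append(float(fit.rates[i]))
        off_ses.append(float(fit.rates[i] / np.sqrt(max(n_eff, 1.0))))
    off_series = kin.ConcentrationSeries(
        concentrations=np.array(concs), rates=np.array(off_rates),
        ses=np.array(off_ses), label=f"{bound}-exit (dissociation)",
    )
    off_test = kin.test_concentration_independence(off_series, alpha=cfg.alpha)

    kd, kd_se = kin.apparent_kd(
        kon_fit.slope, off_test["pooled_rate"],
        kon_fit.slope_se, off_test["pooled_se"],
    )

    report = {
        "seed": seed,
        "config_digest": cfg.digest(),
        "k_on": {"slope": kon_fit.slope, "se": kon_fit.slope_se,
                 "intercept": kon_fit.intercept, "mode": kon_fit.mode,
                 "component_rank": int(rank_on), "concentration_corr": corr},
        "k_off": off_test,
        "apparent_kd_nM": {"value": kd, "se": kd_se},
        "per_concentration": {
            str(c): {
                "n_traces": results[c]["n_traces"],
                "n_accepted": results[c]["n_accepted"],
                "low": _fit_summary(results[c]["low_fit"], results[c]["low_choice"]),
                "high": _fit_summary(results[c]["high_fit"], results[c]["high_choice"]),
            }
            for c in concs
        },
        "log": log,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=float)
        )
        pd.DataFrame(
            [
                {"concentration_nM": c,
                 "k_obs_binding": results[c][f"{unbound}_fit"].primary_rate,
                 "k_obs_dissociation": results[c][f"{bound}_fit"].primary_rate}
                for c in concs
            ]
        ).to_csv(out / "rates.tsv", sep="\t", index=False)
        (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return report


def _fit_summary(fit, choice) -> dict:
    return {
        "n_components": fit.n_components,
        "rates": [float(r) for r in fit.rates],
        "amplitudes": [float(a) for a in fit.amplitudes],
        "loglik": fit.loglik,
        "llr": choice.llr,
        "p_value": choice.p_value,
        "n_dwells": fit.n,
        "flags": list(fit.flags),
    }
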
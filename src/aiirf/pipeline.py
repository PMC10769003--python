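"""Simulate → analyze → summarize experiment orchestration.

The figure-level experiment designs (spot-diameter series across backgrounds,
NBQX pathway block, TTX/HEPES surround dissection, annulus surround probes,
ganglion-cell inheritance) are packaged as named, reproducible experiments
that run the generator with the shipped calibration and compare the simulated
population statistics against the packaged reference values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, stats, synth
from .calibration import (
    load_default_params,
    load_reference_targets,
    protocol_contrast,
)
from .containers import DEFAULT_FS_HZ, SpikeTrialSet, TrialSet
from .metrics import UndefinedMetricError
from .stim import (
    DEFAULT_DIAMETERS_UM,
    StimulusEpoch,
    make_annulus_protocol,
    make_spot_protocol,
)
from .synth import CircuitParams, Condition

__all__ = [
    "ExperimentConfig",
    "spot_series_experiment",
    "peak_88um_experiment",
    "nbqx_reduction_experiment",
    "annulus_experiment",
    "run_experiment",
    "reproduce",
    "list_experiments",
    "write_trialset",
    "read_trialset",
]

_VERSION = "0.1.0"


# ------------------------------------------------------------ experiment runs

def _response_metric(ts, mode: str) -> float:
    """The mode-appropriate response measure: peak ΔV (PSP), charge (currents), count (spikes)."""
    if isinstance(ts, SpikeTrialSet):
        _, mean = metrics.spike_count(ts)
        return mean
    ts = metrics.baseline_subtract(ts)
    if mode == "PSP":
        return metrics.peak_depolarization(ts)
    return metrics.charge(ts)


def spot_series_experiment(
    background: float,
    condition: Condition,
    params: CircuitParams | None = None,
    n_cells: int = 13,
    n_trials: int = 4,
    seed: int = 0,
    diameters_um=DEFAULT_DIAMETERS_UM,
    contrast: float | None = None,
    epsilon: float = 0.05,
    fs_hz: float = DEFAULT_FS_HZ,
) -> pd.DataFrame:
    """Spot-diameter series for a cell population.

    Returns one row per cell with the per-cell surround-suppression index,
    receptive-field-center size and 88-um response, plus the per-diameter
    responses in wide columns (``resp_<d>``).
    """
    params = params or load_default_params()
    contrast = contrast if contrast is not None else protocol_contrast(condition)
    protocol = make_spot_protocol(
        diameters_um, contrast=contrast, background_rstar=background
    )
    pop = synth.simulate_population(
        protocol, condition, params, n_cells, n_trials, seed, fs_hz
    )
    rows = []
    for cell_id, per_epoch in pop.items():
        diam = [ts.epoch.diameter_um for ts in per_epoch.values()]
        resp = [_response_metric(ts, condition.mode) for ts in per_epoch.values()]
        curve = metrics.size_tuning(resp, diam)
        row = {
            "cell_id": cell_id,
            "background_rstar": background,
            "condition": condition.label,
            "ssi": metrics.ssi(curve),
            "rf_center_um": metrics.rf_center_size(curve, epsilon),
        }
        for d, r in zip(curve.diameters_um, curve.resp):
            row[f"resp_{d:g}"] = r
        rows.append(row)
    return pd.DataFrame(rows)


def peak_88um_experiment(
    background: float,
    params: CircuitParams | None = None,
    n_cells: int = 13,
    n_trials: int = 4,
    seed: int = 0,
    condition: Condition = Condition(mode="PSP"),
    fs_hz: float = DEFAULT_FS_HZ,
) -> pd.DataFrame:
    """Per-cell peak depolarization to the 88-um, +100% contrast spot."""
    params = params or load_default_params()
    protocol = make_spot_protocol([88.0], background_rstar=background)
    pop = synth.simulate_population(protocol, condition, params, n_cells, n_trials, seed, fs_hz)
    rows = [
        {
            "cell_id": cid,
            "peak_mv": metrics.peak_depolarization(
                metrics.baseline_subtract(next(iter(per.values())))
            ),
        }
        for cid, per in pop.items()
    ]
    return pd.DataFrame(rows)


def nbqx_reduction_experiment(
    background: float,
    params: CircuitParams | None = None,
    n_cells: int = 6,
    n_trials: int = 4,
    seed: int = 0,
    diameter_um: float = 88.0,
    fs_hz: float = DEFAULT_FS_HZ,
) -> pd.DataFrame:
    """Paired control / NBQX EPSC charge for one spot; per-cell percent reduction."""
    params = params or load_default_params()
    protocol = make_spot_protocol([diameter_um], background_rstar=background)
    ctrl = synth.simulate_population(
        protocol, Condition(mode="EPSC"), params, n_cells, n_trials, seed, fs_hz
    )
    drug = synth.simulate_population(
        protocol, Condition(mode="EPSC", drugs={"NBQX"}), params, n_cells, n_trials, seed, fs_hz
    )
    rows = []
    for cid in ctrl:
        q_c = metrics.charge(metrics.baseline_subtract(next(iter(ctrl[cid].values()))))
        q_d = metrics.charge(metrics.baseline_subtract(next(iter(drug[cid].values()))))
        rows.append(
            {"cell_id": cid, "charge_ctrl_pc": q_c, "charge_nbqx_pc": q_d,
             "reduction_pct": 100.0 * (1.0 - q_d / q_c)}
        )
    return pd.DataFrame(rows)


def annulus_experiment(
    background: float,
    params: CircuitParams | None = None,
    n_cells: int = 10,
    n_trials: int = 4,
    seed: int = 0,
    contrast: float = 1.0,
    condition: Condition = Condition(mode="PSP"),
    fs_hz: float = DEFAULT_FS_HZ,
) -> pd.DataFrame:
    """Surround-only probe: per-cell transient peak and sustained level."""
    params = params or load_default_params()
    protocol = make_annulus_protocol([contrast], background_rstar=background)
    pop = synth.simulate_population(protocol, condition, params, n_cells, n_trials, seed, fs_hz)
    rows = []
    for cid, per in pop.items():
        ts = metrics.baseline_subtract(next(iter(per.values())))
        transient, sustained = metrics.annulus_metrics(ts)
        rows.append(
            {"cell_id": cid, "transient_peak_mv": transient, "sustained_mv": sustained}
        )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- run directory

@dataclass
class ExperimentConfig:
    """A declarative simulate→analyze run."""

    name: str
    protocol: list            # list of StimulusEpoch or epoch dicts
    conditions: list          # list of Condition or condition dicts
    background_rstar: float
    n_cells: int = 8
    n_trials: int = 4
    seed: int = 0
    epsilon: float = 0.05
    calibration: str | None = None  # path to a YAML calibration; None = shipped default
    save_traces: bool = False

    def resolve(self) -> tuple[list[StimulusEpoch], list[Condition], CircuitParams]:
        epochs = [
            e if isinstance(e, StimulusEpoch) else StimulusEpoch.from_dict(e)
            for e in self.protocol
        ]
        conds = [c if isinstance(c, Condition) else _condition_from_dict(c) for c in self.conditions]
        if self.calibration is None:
            params = load_default_params()
        else:
            from .calibration import load_params

            params = load_params(self.calibration)
        return epochs, conds, params

    def digest(self) -> str:
        blob = json.dumps(
            {
                "name": self.name,
                "protocol": [e.to_dict() if isinstance(e, StimulusEpoch) else e for e in self.protocol],
                "conditions": [
                    _condition_to_dict(c) if isinstance(c, Condition) else c for c in self.conditions
                ],
                "background_rstar": self.background_rstar,
                "n_cells": self.n_cells,
                "n_trials": self.n_trials,
                "seed": self.seed,
                "epsilon": self.epsilon,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _condition_to_dict(c: Condition) -> dict:
    return {"genotype": c.genotype, "drugs": sorted(c.drugs), "mode": c.mode, "cell": c.cell}


def _condition_from_dict(d: dict) -> Condition:
    return Condition(
        genotype=d.get("genotype", "WT"),
        drugs=frozenset(d.get("drugs", ())),
        mode=d.get("mode", "PSP"),
        cell=d.get("cell", "AII"),
    )


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Run a config to a ``run/{traces,metrics.csv,summary.json,manifest.json}`` directory."""
    epochs, conds, params = config.resolve()
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)

    rows = []
    summary: dict = {"conditions": {}}
    for cond in conds:
        pop = synth.simulate_population(
            epochs, cond, params, config.n_cells, config.n_trials, config.seed
        )
        per_metric: dict[str, list] = {}
        for cid, per_epoch in pop.items():
            for label, ts in per_epoch.items():
                val = _response_metric(ts, cond.mode)
                units = "count" if cond.mode == "spikes" else (
                    "mV" if cond.mode == "PSP" else "pC"
                )
                rows.append(
                    {"cell_id": cid, "condition": cond.label, "epoch": label,
                     "metric": "response", "value": val, "units": units}
                )
                if config.save_traces and isinstance(ts, TrialSet):
                    write_trialset(ts, out / "traces" / f"{cond.label}_{cid}_{label}")
            diam = [ts.epoch.diameter_um for ts in per_epoch.values()]
            if all(d is not None for d in diam) and 1200.0 in diam:
                resp = [_response_metric(ts, cond.mode) for ts in per_epoch.values()]
                curve = metrics.size_tuning(resp, diam)
                try:
                    rows.append(
                        {"cell_id": cid, "condition": cond.label, "epoch": "series",
                         "metric": "ssi", "value": metrics.ssi(curve), "units": ""}
                    )
                except UndefinedMetricError:
                    pass
                rows.append(
                    {"cell_id": cid, "condition": cond.label, "epoch": "series",
                     "metric": "rf_center", "value": metrics.rf_center_size(curve, config.epsilon),
                     "units": "um"}
                )
        df = pd.DataFrame(rows)
        cond_summary = {}
        for metric_name, grp in df[df.condition == cond.label].groupby("metric"):
            vals = grp.value.to_numpy()
            if vals.size >= 2:
                s = stats.mean_sem(vals)
                cond_summary[metric_name] = {"n": s.n, "mean": s.mean, "sem": s.sem}
            else:
                cond_summary[metric_name] = {
                    "n": int(vals.size), "mean": float(vals.mean()), "sem": None,
                    "note": "sem undefined for n < 2",
                }
        summary["conditions"][cond.label] = cond_summary

    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "manifest.json").write_text(
        json.dumps(
            {"package_version": _VERSION, "seed": config.seed,
             "config_hash": config.digest(), "name": config.name},
            indent=2,
        )
    )
    return out


# --------------------------------------------------------- builtin experiments

def _ref(key: str, bg: float) -> float:
    df = load_reference_targets()
    row = df[(df.key == key) & (np.isclose(df.background_rstar, bg))]
    return float(row.value.iloc[0])


def _exp_psp_spot_series(params, seed):
    rows = []
    for bg, n in ((0.5, 13), (500.0, 13), (25000.0, 12)):
        df = spot_series_experiment(bg, Condition(mode="PSP"), params, n, seed=seed)
        s = stats.mean_sem(df.ssi)
        rows.append(
            {"quantity": "psp_ssi", "background_rstar": bg, "simulated": s.mean,
             "sem": s.sem, "n": s.n, "reference": _ref("psp_ssi", bg)}
        )
    return pd.DataFrame(rows)


def _exp_nbqx(params, seed):
    rows = []
    for bg in (0.5, 500.0, 25000.0):
        df = nbqx_reduction_experiment(bg, params, n_cells=6, seed=seed)
        s = stats.mean_sem(df.reduction_pct)
        rows.append(
            {"quantity": "nbqx_charge_reduction_pct", "background_rstar": bg,
             "simulated": s.mean, "sem": s.sem, "n": s.n,
             "reference": _ref("nbqx_charge_reduction_pct", bg)}
        )
    return pd.DataFrame(rows)


def _exp_epsc_ttx_hepes(params, seed):
    rows = []
    cases = [
        ("epsc_ssi_control", frozenset(), {0.5: 6, 500.0: 8, 25000.0: 10}),
        ("epsc_ssi_ttx", frozenset({"TTX"}), {0.5: 6, 500.0: 8, 25000.0: 10}),
        ("epsc_ssi_ttx_hepes", frozenset({"TTX", "HEPES"}), {500.0: 5, 25000.0: 6}),
    ]
    for key, drugs, ns in cases:
        for bg, n in ns.items():
            df = spot_series_experiment(
                bg, Condition(mode="EPSC", drugs=drugs), params, n, seed=seed
            )
            s = stats.mean_sem(df.ssi)
            rows.append(
                {"quantity": key, "background_rstar": bg, "simulated": s.mean,
                 "sem": s.sem, "n": s.n, "reference": _ref(key, bg)}
            )
    return pd.DataFrame(rows)


def _exp_gabac(params, seed):
    rows = []
    for bg in (500.0, 25000.0):
        for drugs, label in ((frozenset({"gabazine"}), "gabazine"),
                             (frozenset({"gabazine", "TPMPA"}), "gabazine+TPMPA")):
            df = spot_series_experiment(
                bg, Condition(mode="EPSC", drugs=drugs), params, n_cells=4, seed=seed
            )
            s = stats.mean_sem(df.ssi)
            rows.append(
                {"quantity": f"epsc_ssi_{label}", "background_rstar": bg,
                 "simulated": s.mean, "sem": s.sem, "n": s.n, "reference": np.nan}
            )
    return pd.DataFrame(rows)


def _exp_annulus(params, seed):
    rows = []
    for bg, ref in ((0.5, 0.0), (500.0, -3.3), (25000.0, -4.5)):
        df = annulus_experiment(bg, params, n_cells=10, seed=seed)
        s = stats.mean_sem(df.transient_peak_mv)
        rows.append(
            {"quantity": "annulus_transient_mv", "background_rstar": bg,
             "simulated": s.mean, "sem": s.sem, "n": s.n, "reference": ref}
        )
    return pd.DataFrame(rows)


def _exp_sinusoid(params, seed):
    from .stim import make_sinusoid_protocol

    rows = []
    for bg in (0.5, 25000.0):
        for freq in (0.61, 2.43, 4.86):
            protocol = make_sinusoid_protocol([freq], [100.0, 1000.0], background_rstar=bg)
            pop = synth.simulate_population(
                protocol, Condition(mode="PSP"), params, n_cells=8, n_trials=4, seed=seed
            )
            for d in (100.0, 1000.0):
                ris = []
                for per in pop.values():
                    ts = next(
                        t for t in per.values() if t.epoch.diameter_um == d
                    )
                    cyc = metrics.cycle_response(metrics.baseline_subtract(ts))
                    ris.append(metrics.rectification_index(cyc))
                s = stats.mean_sem(ris)
                rows.append(
                    {"quantity": "rectification_index", "background_rstar": bg,
                     "freq_hz": freq, "diameter_um": d, "simulated": s.mean,
                     "sem": s.sem, "n": s.n, "reference": np.nan}
                )
    return pd.DataFrame(rows)


def _exp_nnos(params, seed):
    rows = []
    for bg, n in ((500.0, 8), (25000.0, 6)):
        for genotype in ("WT", "nNOS_ablated"):
            df = spot_series_experiment(
                bg, Condition(genotype=genotype, mode="PSP"), params, n, seed=seed
            )
            s = stats.mean_sem(df.ssi)
            rows.append(
                {"quantity": f"psp_ssi_{genotype}", "background_rstar": bg,
                 "simulated": s.mean, "sem": s.sem, "n": s.n,
                 "reference": _ref("psp_ssi", bg) if genotype == "WT" else np.nan}
            )
    return pd.DataFrame(rows)


def _exp_rgc(params, seed):
    rows = []
    for genotype, ref_key in (("WT", "rgc_spike_ssi"), ("Cx36KO", "rgc_spike_ssi_cx36ko")):
        cond = Condition(genotype=genotype, mode="spikes", cell="sONalpha")
        df = spot_series_experiment(25000.0, cond, params, n_cells=5, seed=seed)
        s = stats.mean_sem(df.ssi)
        rows.append(
            {"quantity": ref_key, "background_rstar": 25000.0, "simulated": s.mean,
             "sem": s.sem, "n": s.n, "reference": _ref(ref_key, 25000.0)}
        )
    return pd.DataFrame(rows)


EXPERIMENTS = {
    "psp_spot_series": _exp_psp_spot_series,
    "nbqx_pathway": _exp_nbqx,
    "epsc_ttx_hepes": _exp_epsc_ttx_hepes,
    "gabac_presynaptic": _exp_gabac,
    "annulus_surround": _exp_annulus,
    "sinusoid_rectification": _exp_sinusoid,
    "nnos_ablation": _exp_nnos,
    "rgc_inheritance": _exp_rgc,
}


def list_experiments() -> list[str]:
    return sorted(EXPERIMENTS)


def reproduce(
    name: str, seed: int = 0, params: CircuitParams | None = None
) -> pd.DataFrame:
    """Run a builtin figure-level experiment; returns simulated-vs-reference rows."""
    if name not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {name!r}; valid ids: {', '.join(list_experiments())}"
        )
    params = params or load_default_params()
    return EXPERIMENTS[name](params, seed)


# ------------------------------------------------------------------ trace I/O

_REQUIRED_SIDECAR = ("fs_hz", "units", "epoch", "cell_id", "n_trials")


def write_trialset(ts: TrialSet, path_base: str | Path) -> tuple[Path, Path]:
    """CSV (time_s, trial_1..n) + JSON sidecar container for one trial bundle."""
    base = Path(path_base)
    csv_path, json_path = base.with_suffix(".csv"), base.with_suffix(".json")
    df = pd.DataFrame({"time_s": ts.times})
    for i in range(ts.n_trials):
        df[f"trial_{i + 1}"] = ts.traces[i]
    df.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "fs_hz": ts.fs_hz,
        "units": ts.units,
        "epoch": ts.epoch.to_dict(),
        "cell_id": ts.cell_id,
        "n_trials": ts.n_trials,
        "seed": ts.seed,
        "condition": _condition_to_dict(ts.condition)
        if isinstance(ts.condition, Condition)
        else ts.condition,
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path


def read_trialset(path_base: str | Path) -> TrialSet:
    """Read the CSV + JSON-sidecar container back into a :class:`TrialSet`."""
    base = Path(path_base)
    csv_path, json_path = base.with_suffix(".csv"), base.with_suffix(".json")
    if not json_path.exists():
        raise FileNotFoundError(f"missing sidecar {json_path}")
    sidecar = json.loads(json_path.read_text())
    for key in _REQUIRED_SIDECAR:
        if key not in sidecar:
            raise ValueError(f"sidecar schema violation: missing required field {key!r}")
    df = pd.read_csv(csv_path)
    trial_cols = [c for c in df.columns if c.startswith("trial_")]
    if len(trial_cols) != sidecar["n_trials"]:
        raise ValueError(
            f"sidecar schema violation: n_trials={sidecar['n_trials']} but "
            f"{len(trial_cols)} trial columns present"
        )
    cond = sidecar.get("condition")
    return TrialSet(
        traces=df[trial_cols].to_numpy().T,
        fs_hz=float(sidecar["fs_hz"]),
        units=sidecar["units"],
        epoch=StimulusEpoch.from_dict(sidecar["epoch"]),
        cell_id=sidecar.get("cell_id", ""),
        condition=_condition_from_dict(cond) if isinstance(cond, dict) else cond,
        seed=sidecar.get("seed"),
    )
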
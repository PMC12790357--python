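"""End-to-end monitoring pipeline: dataset directory → JSON decision report.

A dataset directory holds one CSV per acquisition plus a ``manifest.json``
describing the frames (written by the ``specmon simulate`` commands; any
producer can emit the same layout):

.. code-block:: json

    {"axis_unit": "nm", "technique": "UVVIS", "mode": "absorption",
     "frames": [{"file": "frame_0000.csv", "time": 0.0}, ...]}

:func:`run_pipeline` loads the frames, integrates derivative-mode (EPR)
data, resolves the epsilon policy, computes the similarity trace, applies
the Spearman noise gate and plateau detection, classifies the kinetic
profile and attaches the matching kinetic fit.  Every threshold used is
echoed in the report's ``effective_config`` block.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import config as defaults
from . import kinetics, monitor, preprocess, similarity, spectra_io
from .datatypes import Mode, SimilarityTrace, SpectrumSeries, Technique
from .errors import SpecmonError, ValidationError

logger = logging.getLogger("specmon")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_IO = 3


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run; all defaults visible."""

    metric: str = "jaccard"
    reference: str = "first"
    epsilon: str | float = "auto"     # "auto" => multiplier x estimated sigma
    epsilon_multiplier: float = defaults.EPSILON_SIGMA_MULTIPLIER
    window: tuple[float, float] | None = None
    plateau_window: int = defaults.PLATEAU_WINDOW
    slope_threshold: float = defaults.PLATEAU_SLOPE_THRESHOLD
    gate_rho_min: float = defaults.GATE_RHO_MIN
    gate_n_perm: int = defaults.GATE_N_PERM
    osc_power_fraction: float = defaults.OSC_POWER_FRACTION_MIN
    aicc_margin: float = defaults.AICC_MARGIN
    block_size: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window) if self.window else None
        return d


def load_dataset(path) -> SpectrumSeries:
    """Load a dataset directory (manifest.json + per-frame CSVs)."""
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {root}")
    manifest = json.loads(manifest_path.read_text())
    spectra = []
    for frame in manifest["frames"]:
        s = spectra_io.read_spectrum_csv(
            root / frame["file"],
            axis_unit=manifest.get("axis_unit", ""),
            time=float(frame["time"]),
            technique=Technique(manifest.get("technique", "OTHER")),
            mode=Mode(manifest.get("mode", "absorption")),
        )
        spectra.append(s)
    return spectra_io.resample_series(spectra)


def save_dataset(series: SpectrumSeries, path, extra_meta: dict | None = None) -> None:
    """Write a series as a dataset directory consumable by :func:`load_dataset`."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    frames = []
    for i, s in enumerate(series):
        name = f"frame_{i:04d}.csv"
        spectra_io.write_spectrum_csv(s, root / name)
        frames.append({"file": name, "time": s.time})
    manifest = {
        "axis_unit": series.axis_unit,
        "technique": series[0].technique.value,
        "mode": series[0].mode.value,
        "frames": frames,
    }
    if extra_meta:
        manifest["meta"] = extra_meta
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _resolve_epsilon(series: SpectrumSeries, cfg: RunConfig) -> float:
    if isinstance(cfg.epsilon, (int, float)):
        return float(cfg.epsilon)
    if str(cfg.epsilon).lower() == "auto":
        est = preprocess.estimate_error(series)
        return cfg.epsilon_multiplier * est.sigma
    return float(cfg.epsilon)


def analyze_series(series: SpectrumSeries, cfg: RunConfig | None = None) -> dict:
    """Run the decision pipeline on an in-memory series; returns the report dict."""
    cfg = cfg or RunConfig()
    if series[0].mode == Mode.DERIVATIVE:
        logger.info("derivative-mode data: integrating to absorption mode")
        series = SpectrumSeries(
            spectra=[preprocess.integrate_derivative(s) for s in series]
        )
    if cfg.block_size > 1:
        series = preprocess.block_average(series, cfg.block_size)

    eps = _resolve_epsilon(series, cfg)
    if cfg.metric == "jaccard":
        series = SpectrumSeries(
            spectra=[preprocess.enforce_nonnegative(s, epsilon=5 * eps if eps > 0 else 1e-9)
                     for s in series]
        )
    trace = similarity.similarity_trace(
        series, metric=cfg.metric, reference=cfg.reference,
        epsilon=eps, window=cfg.window,
    )
    return analyze_trace(trace, cfg)


def analyze_trace(trace: SimilarityTrace, cfg: RunConfig | None = None) -> dict:
    """Gate, plateau-detect and classify an existing similarity trace."""
    cfg = cfg or RunConfig()
    gate = monitor.spearman_gate(
        trace, rho_min=cfg.gate_rho_min, n_perm=cfg.gate_n_perm, seed=cfg.seed
    )
    plateau = monitor.detect_plateau(
        trace, window=cfg.plateau_window, slope_threshold=cfg.slope_threshold
    )
    label = monitor.classify_profile(
        trace, rho_min=cfg.gate_rho_min, n_perm=cfg.gate_n_perm, seed=cfg.seed,
        power_fraction_min=cfg.osc_power_fraction, aicc_margin=cfg.aicc_margin,
    )

    report: dict = {
        "effective_config": cfg.to_dict(),
        "trace": {
            "times": trace.times.tolist(),
            "values": trace.values.tolist(),
            "metric": trace.metric,
            "reference": trace.reference,
            "epsilon": trace.epsilon,
        },
        "gate": dataclasses.asdict(gate),
        "plateau": {
            "detected": plateau.detected,
            "onset_index": plateau.onset_index,
            "onset_time": plateau.onset_time,
            "window": plateau.window,
            "slope_threshold": plateau.slope_threshold,
        },
        "class": label.value,
    }
    if label == monitor.ProfileClass.OSCILLATORY:
        osc = kinetics.detect_oscillation(trace)
        report["kinetics"] = {
            "model": "oscillation",
            "period": osc.period,
            "frequency": osc.frequency,
            "power_fraction": osc.power_fraction,
        }
    elif label == monitor.ProfileClass.FIRST_ORDER:
        fit = kinetics.fit_exponential(trace)
        report["kinetics"] = {
            "model": fit.model.value, "params": fit.params,
            "stderr": fit.stderr, "rss": fit.rss, "aicc": fit.aicc,
            "converged": fit.converged,
        }
    elif label == monitor.ProfileClass.SIGMOIDAL:
        fit = kinetics.fit_sigmoid(trace)
        report["kinetics"] = {
            "model": fit.model.value, "params": fit.params,
            "stderr": fit.stderr, "rss": fit.rss, "aicc": fit.aicc,
            "converged": fit.converged,
        }
    return report


def run_pipeline(input_dir, cfg: RunConfig | None = None, out_path=None) -> tuple[int, dict]:
    """Full pipeline over a dataset directory.

    Returns ``(exit_status, report)``: 0 on success, 2 on validation error,
    3 on I/O error.  The report is also written to ``out_path`` when given.
    """
    try:
        series = load_dataset(input_dir)
        report = analyze_series(series, cfg)
    except (FileNotFoundError, OSError, json.JSONDecodeError) as exc:
        logger.error("I/O error: %s", exc)
        return EXIT_IO, {"error": str(exc)}
    except (ValidationError, SpecmonError) as exc:
        logger.error("validation error: %s", exc)
        return EXIT_VALIDATION, {"error": str(exc)}
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2))
    return EXIT_OK, report
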
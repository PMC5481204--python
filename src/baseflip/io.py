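"""Plain-text file formats, configuration and report serialisation.

Histogram tables are two-column text files (time_ns, counts) with
'#'-prefixed metadata lines; pipeline configuration round-trips through
YAML; analysis results are written as a JSON report with full
provenance (configuration, seeds, library versions) plus a
human-readable per-sample decay-parameter table.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from .conformers import ConformerReport, StateThresholds, VerdictThresholds
from .fitting import FitOptions, GlobalFitResult
from .geometry import GeometryReport
from .simulate import AcquisitionSettings, TCSPCMeasurement

__all__ = [
    "HistogramFormatError",
    "PipelineConfig",
    "read_histogram_table",
    "write_histogram_table",
    "write_report",
    "read_report",
]


class HistogramFormatError(ValueError):
    """Raised for malformed histogram table files."""


def write_histogram_table(measurement: TCSPCMeasurement, path: str | Path) -> None:
    """Write a measurement as a commented two-column text table."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# label: {measurement.label}\n")
        fh.write(f"# wavelength_nm: {measurement.emission_wavelength:g}\n")
        fh.write("# columns: time_ns counts\n")
        for t, c in zip(measurement.time_axis, measurement.counts):
            fh.write(f"{t:.9f}\t{int(round(c))}\n")


def read_histogram_table(path: str | Path) -> TCSPCMeasurement:
    """Read a histogram table, validating grid uniformity and counts.

    Metadata lines ``# label: ...`` and ``# wavelength_nm: ...`` are
    required.  Counts must be non-negative integers; the time grid must
    be uniform within 1e-6 relative.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    times, counts = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise HistogramFormatError(f"{path}:{lineno}: expected two columns")
        try:
            t = float(parts[0])
            c = float(parts[1])
        except ValueError:
            raise HistogramFormatError(f"{path}:{lineno}: non-numeric entry") from None
        if c < 0:
            raise HistogramFormatError(f"{path}:{lineno}: negative count {parts[1]}")
        if c != int(c):
            raise HistogramFormatError(f"{path}:{lineno}: non-integer count {parts[1]}")
        times.append(t)
        counts.append(int(c))
    if "label" not in meta or "wavelength_nm" not in meta:
        raise HistogramFormatError(
            f"{path}: missing required metadata (label, wavelength_nm)"
        )
    if len(times) < 2:
        raise HistogramFormatError(f"{path}: need at least 2 channels")
    t = np.array(times)
    steps = np.diff(t)
    dt = steps.mean()
    if np.any(steps <= 0) or np.any(np.abs(steps - dt) > 1e-6 * dt):
        raise HistogramFormatError(f"{path}: non-uniform time grid")
    return TCSPCMeasurement(
        time_axis=t,
        counts=np.array(counts),
        emission_wavelength=float(meta["wavelength_nm"]),
        label=meta["label"],
    )


@dataclass
class PipelineConfig:
    """Full configuration of a simulate -> fit -> analyze pipeline run."""

    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)
    fit: FitOptions = field(default_factory=FitOptions)
    states: StateThresholds = field(default_factory=StateThresholds)
    verdict: VerdictThresholds = field(default_factory=VerdictThresholds)
    n_components: int = 4
    samples: list[str] = field(
        default_factory=lambda: ["TP1_free", "TP1_bound", "TP13_free", "TP13_bound"]
    )
    master_seed: int = 0
    output_dir: str = "baseflip-output"

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        kwargs = dict(raw)
        converters = {
            "acquisition": AcquisitionSettings,
            "fit": FitOptions,
            "states": StateThresholds,
            "verdict": VerdictThresholds,
        }
        for key, typ in converters.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                if key == "acquisition" and "emission_wavelengths" in sub:
                    sub["emission_wavelengths"] = tuple(sub["emission_wavelengths"])
                kwargs[key] = typ(**sub)
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())


def _format_lifetime(tau_ns: float) -> str:
    """Render ns lifetimes, switching to ps below 1 ns."""
    if tau_ns < 1.0:
        return f"{tau_ns * 1000:.0f} ps"
    return f"{tau_ns:.2f} ns"


def _fit_to_dict(fit: GlobalFitResult) -> dict:
    return {
        "shared_lifetimes_ns": [float(t) for t in fit.shared_lifetimes],
        "chi2_reduced_global": fit.chi2_reduced_global,
        "converged": fit.converged,
        "n_evaluations": fit.n_evaluations,
        "parameter_uncertainties": fit.parameter_uncertainties,
        "per_measurement": {
            f"{label}@{wl:g}nm": {
                "A_factors": [float(a) for a in pm.amplitudes],
                "scale": pm.scale,
                "background": pm.background,
                "irf_shift_ns": pm.irf_shift,
                "chi2_reduced": pm.chi2_reduced,
            }
            for (label, wl), pm in fit.per_measurement.items()
        },
    }


def decay_parameter_table(fits: dict[str, GlobalFitResult]) -> str:
    """Per-sample table of fitted A-factors and lifetimes.

    One row per sample/condition with four (A, tau) columns, mirroring
    how multi-component 2AP decay parameters are conventionally
    tabulated.
    """
    lines = []
    header = ["sample".ljust(12)] + [f"A{i}     tau{i}".ljust(17) for i in range(1, 5)]
    lines.append(" | ".join(header))
    lines.append("-" * len(lines[0]))
    for name, fit in fits.items():
        amps = fit.mean_amplitudes()
        cells = [name.ljust(12)]
        for i in range(4):
            if i < len(amps):
                a = f"{amps[i]:.3f}"
                t = _format_lifetime(float(fit.shared_lifetimes[i]))
                cells.append(f"{a}  {t}".ljust(17))
            else:
                cells.append("-".ljust(17))
        lines.append(" | ".join(cells))
    return "\n".join(lines)


def write_report(
    path: str | Path,
    fits: dict[str, GlobalFitResult] | None = None,
    conformers: dict[str, ConformerReport] | None = None,
    geometry: GeometryReport | None = None,
    config: PipelineConfig | None = None,
    seeds: dict[str, int] | None = None,
) -> None:
    """Write the JSON analysis report (plus a text summary alongside).

    Provenance (config, seeds, versions) is embedded; the only
    non-deterministic field is ``generated_at``.
    """
    import scipy

    import baseflip

    path = Path(path)
    report: dict = {
        "provenance": {
            "package": "baseflip",
            "version": baseflip.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "config": asdict(config) if config else None,
            "seeds": seeds or {},
        },
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }
    if fits:
        report["fits"] = {name: _fit_to_dict(fit) for name, fit in fits.items()}
    if conformers:
        report["conformers"] = {
            name: json.loads(rep.to_json()) for name, rep in conformers.items()
        }
    if geometry:
        report["geometry"] = geometry.to_dict()
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    summary = []
    if fits:
        summary.append(decay_parameter_table(fits))
    if conformers:
        for name, rep in conformers.items():
            summary.append(f"\n== {name} ==\n{rep.summary()}")
    if summary:
        path.with_suffix(".txt").write_text("\n".join(summary) + "\n")


def read_report(path: str | Path) -> dict:
    """Load a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
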
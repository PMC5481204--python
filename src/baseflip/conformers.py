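"""Conformational-population analysis of fitted 2AP decay components.

Each decay component of an intra-helical fluorescent base analogue maps
to a conformational state of the duplex: strong stacking quenches the
probe (short lifetime), an extra-helical, solvent-exposed base is
unquenched (long lifetime), and imperfectly stacked intra-helical
conformations fall in between.  The A-factor of a component is read as
the fractional occupancy of its state, so comparing the fitted
populations of a free duplex with the protein-bound complex quantifies
any protein-induced transfer of population between states — the
signature of dynamic base flipping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .fitting import GlobalFitResult

__all__ = [
    "StateThresholds",
    "VerdictThresholds",
    "ConformerReport",
    "STATES",
    "classify_components",
    "state_populations",
    "population_transfer",
    "steady_state_ratio",
    "flipping_verdict",
    "build_report",
]

STATES = ("stacked", "intermediate", "unstacked")


@dataclass(frozen=True)
class StateThresholds:
    """Lifetime boundaries (ns) between conformational states.

    Components with tau below ``stacked_below`` are called stacked, with
    tau at or above ``unstacked_from`` unstacked, otherwise
    intermediate.  Defaults separate the canonical stacked (30-80 ps)
    and unstacked (7.5-10 ns) 2AP lifetimes from the intermediates
    (~0.5 and ~2 ns) with wide margins.
    """

    stacked_below: float = 0.2
    unstacked_from: float = 4.0


@dataclass(frozen=True)
class VerdictThresholds:
    """Population-transfer thresholds (percentage points) for the verdict."""

    flip_points: float = 15.0
    no_change_points: float = 5.0


@dataclass
class ConformerReport:
    """Population analysis of a free-vs-bound pair of global fits."""

    populations: dict[str, dict[str, float]]
    transfer: dict[str, float]
    brightness_ratio: float
    verdict: str
    notes: str = field(
        default="brightness_ratio is the amplitude-weighted-lifetime proxy "
        "for relative steady-state intensity, not a calibrated yield ratio"
    )

    def to_json(self) -> str:
        return json.dumps(
            {
                "populations": self.populations,
                "transfer_points": self.transfer,
                "brightness_ratio": self.brightness_ratio,
                "verdict": self.verdict,
                "notes": self.notes,
            },
            indent=2,
        )

    def summary(self) -> str:
        lines = ["Conformer population analysis", "-" * 32]
        for condition, pops in self.populations.items():
            row = ", ".join(f"{s}: {100 * p:.1f}%" for s, p in pops.items())
            lines.append(f"{condition:>6}: {row}")
        row = ", ".join(f"{s}: {d:+.1f} pts" for s, d in self.transfer.items())
        lines.append(f"transfer (bound - free): {row}")
        lines.append(f"brightness ratio (proxy): {self.brightness_ratio:.2f}")
        lines.append(f"verdict: {self.verdict}")
        return "\n".join(lines)


def classify_components(
    fit: GlobalFitResult, thresholds: StateThresholds | None = None
) -> list[str]:
    """State label for each shared-lifetime component of a global fit."""
    thresholds = thresholds or StateThresholds()
    taus = np.asarray(fit.shared_lifetimes, dtype=float)
    if np.any(np.diff(taus) < 0):
        raise ValueError("fitted lifetimes must be ascending")
    labels = []
    for tau in taus:
        if tau < thresholds.stacked_below:
            labels.append("stacked")
        elif tau >= thresholds.unstacked_from:
            labels.append("unstacked")
        else:
            labels.append("intermediate")
    return labels


def state_populations(
    fit: GlobalFitResult, thresholds: StateThresholds | None = None
) -> dict[str, float]:
    """Fractional occupancy per state, A-factors averaged over wavelengths."""
    labels = classify_components(fit, thresholds)
    amps = fit.mean_amplitudes()
    pops = {s: 0.0 for s in STATES}
    for label, a in zip(labels, amps):
        pops[label] += float(a)
    return pops


def population_transfer(
    fit_free: GlobalFitResult,
    fit_bound: GlobalFitResult,
    thresholds: StateThresholds | None = None,
) -> dict[str, float]:
    """Signed population change per state (bound - free), in points."""
    pops_free = state_populations(fit_free, thresholds)
    pops_bound = state_populations(fit_bound, thresholds)
    if set(pops_free) != set(pops_bound):
        raise ValueError("state sets differ between conditions")
    return {s: 100.0 * (pops_bound[s] - pops_free[s]) for s in STATES}


def _mean_lifetime(fit: GlobalFitResult) -> float:
    return float(np.dot(fit.mean_amplitudes(), fit.shared_lifetimes))


def steady_state_ratio(fit_free: GlobalFitResult, fit_bound: GlobalFitResult) -> float:
    """Bound/free ratio of amplitude-weighted lifetimes.

    A proxy for the relative steady-state emission intensity of the two
    conditions (identical radiative rates assumed); reported as such,
    not as a calibrated quantum-yield ratio.
    """
    return _mean_lifetime(fit_bound) / _mean_lifetime(fit_free)


def flipping_verdict(
    transfer: dict[str, float],
    brightness_ratio: float | None = None,
    thresholds: VerdictThresholds | None = None,
) -> str:
    """Decide between dynamic_flipping / no_change / indeterminate.

    Dynamic flipping requires a large gain in the unstacked state and a
    matching loss from the stacked state; no_change requires both to be
    small.  ``brightness_ratio`` is advisory (a consistency check) and
    does not alter the decision.
    """
    thresholds = thresholds or VerdictThresholds()
    gain = transfer["unstacked"]
    loss = transfer["stacked"]
    if gain >= thresholds.flip_points and loss <= -thresholds.flip_points:
        return "dynamic_flipping"
    if abs(gain) < thresholds.no_change_points and abs(loss) < thresholds.no_change_points:
        return "no_change"
    return "indeterminate"


def build_report(
    fit_free: GlobalFitResult,
    fit_bound: GlobalFitResult,
    state_thresholds: StateThresholds | None = None,
    verdict_thresholds: VerdictThresholds | None = None,
) -> ConformerReport:
    """Full free-vs-bound conformer analysis of two global fits."""
    transfer = population_transfer(fit_free, fit_bound, state_thresholds)
    ratio = steady_state_ratio(fit_free, fit_bound)
    return ConformerReport(
        populations={
            "free": state_populations(fit_free, state_thresholds),
            "bound": state_populations(fit_bound, state_thresholds),
        },
        transfer=transfer,
        brightness_ratio=ratio,
        verdict=flipping_verdict(transfer, ratio, verdict_thresholds),
    )
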
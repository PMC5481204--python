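"""Multi-exponential fluorescence decay model and IRF reconvolution.

The intensity decay of a fluorophore sampling several quenching
environments is modelled as a sum of exponentials,

    I(t) = sum_i A_i * exp(-t / tau_i),

where ``tau_i`` is the lifetime of component *i* and ``A_i`` its
fractional amplitude (A-factor).  Amplitudes are stored normalised
(``sum A_i = 1``); the absolute intensity of a measurement is carried by
a separate ``scale`` (expected signal photons inside the acquisition
window) plus a flat ``background`` (expected counts per channel).

A recorded TCSPC histogram is the decay convolved with the instrument
response function (IRF) of the counting system.  Two IRF representations
are supported:

* a Gaussian parameterisation (FWHM + centre), convolved analytically
  per component using the exponentially modified Gaussian distribution;
* a measured histogram on the acquisition grid, convolved by circular
  FFT over the laser repetition period so that fluorescence excited by
  preceding pulses wraps around correctly.

All times are in nanoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erfcx, ndtr

__all__ = [
    "DecayComponent",
    "DecayModel",
    "InstrumentResponse",
    "InvalidModelError",
    "evaluate_decay",
    "normalize_amplitudes",
    "amplitude_weighted_lifetime",
    "convolve_irf",
    "ConvolutionEngine",
    "DEFAULT_REPETITION_PERIOD_NS",
]

#: 1 / 4.75 MHz pulse repetition rate, in ns.
DEFAULT_REPETITION_PERIOD_NS = 1e9 / 4.75e6

_GAUSS_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


class InvalidModelError(ValueError):
    """Raised when a decay model violates its invariants."""


@dataclass(frozen=True)
class DecayComponent:
    """One exponential decay component: lifetime tau (ns) and A-factor."""

    lifetime: float
    amplitude: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lifetime) or self.lifetime <= 0:
            raise InvalidModelError(
                f"component lifetime must be positive, got {self.lifetime!r}"
            )
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise InvalidModelError(
                f"component amplitude must be >= 0, got {self.amplitude!r}"
            )


@dataclass(frozen=True)
class DecayModel:
    """A 1-4 component multi-exponential decay.

    Components are kept sorted by ascending lifetime and their
    amplitudes must sum to 1 (within 1e-9).  ``scale`` is the expected
    number of signal photons recorded inside the acquisition window;
    ``background`` the expected counts per channel.  A model with
    ``scale == 0`` represents pure background (the "zero-amplitude"
    limit).
    """

    components: tuple[DecayComponent, ...]
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.components)
        if not 1 <= n <= 4:
            raise InvalidModelError(f"need 1-4 components, got {n}")
        lifetimes = [c.lifetime for c in self.components]
        if any(b < a for a, b in zip(lifetimes, lifetimes[1:])):
            raise InvalidModelError("components must be sorted by ascending lifetime")
        total = sum(c.amplitude for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise InvalidModelError(
                f"amplitudes must sum to 1 (got {total!r}); "
                "use DecayModel.from_arrays to normalise"
            )
        if self.scale < 0:
            raise InvalidModelError("scale must be >= 0")
        if self.background < 0:
            raise InvalidModelError("background must be >= 0")

    @classmethod
    def from_arrays(
        cls,
        amplitudes: Sequence[float],
        lifetimes: Sequence[float],
        scale: float = 1.0,
        background: float = 0.0,
    ) -> "DecayModel":
        """Build a model from raw amplitudes, normalising and sorting."""
        amps = normalize_amplitudes(np.asarray(amplitudes, dtype=float))
        taus = np.asarray(lifetimes, dtype=float)
        if amps.shape != taus.shape:
            raise InvalidModelError("amplitudes and lifetimes must have equal length")
        order = np.argsort(taus, kind="stable")
        comps = tuple(
            DecayComponent(float(taus[i]), float(amps[i])) for i in order
        )
        return cls(comps, scale=float(scale), background=float(background))

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c.amplitude for c in self.components])

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([c.lifetime for c in self.components])

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class InstrumentResponse:
    """Instrument response function, Gaussian-parameterised or measured.

    Exactly one of (``fwhm``, ``center``) or (``grid``, ``histogram``)
    must be provided.  ``repetition_period`` is the laser pulse period
    in ns (default 1/4.75 MHz ~ 210.5 ns).
    """

    fwhm: float | None = None
    center: float | None = None
    grid: np.ndarray | None = field(default=None, repr=False)
    histogram: np.ndarray | None = field(default=None, repr=False)
    repetition_period: float = DEFAULT_REPETITION_PERIOD_NS

    def __post_init__(self) -> None:
        if self.repetition_period <= 0:
            raise InvalidModelError("repetition_period must be > 0")
        if self.is_gaussian:
            if self.histogram is not None or self.grid is not None:
                raise InvalidModelError("give either gaussian or histogram IRF, not both")
            if self.fwhm is None or self.center is None or self.fwhm <= 0:
                raise InvalidModelError("gaussian IRF needs fwhm > 0 and a center")
        else:
            if self.histogram is None or self.grid is None:
                raise InvalidModelError("IRF needs (fwhm, center) or (grid, histogram)")
            hist = np.asarray(self.histogram, dtype=float)
            if hist.ndim != 1 or hist.shape != np.shape(self.grid):
                raise InvalidModelError("IRF histogram and grid must be 1-D, same length")
            if np.any(hist < 0) or hist.sum() <= 0:
                raise InvalidModelError("IRF histogram must be >= 0 with positive sum")

    @property
    def is_gaussian(self) -> bool:
        return self.fwhm is not None or self.center is not None

    @property
    def sigma(self) -> float:
        if not self.is_gaussian:
            raise InvalidModelError("sigma only defined for gaussian IRF")
        return self.fwhm * _GAUSS_FWHM_TO_SIGMA

    @classmethod
    def from_gaussian(
        cls,
        fwhm: float,
        center: float,
        repetition_period: float = DEFAULT_REPETITION_PERIOD_NS,
    ) -> "InstrumentResponse":
        return cls(fwhm=fwhm, center=center, repetition_period=repetition_period)

    @classmethod
    def from_histogram(
        cls,
        grid: np.ndarray,
        histogram: np.ndarray,
        repetition_period: float = DEFAULT_REPETITION_PERIOD_NS,
    ) -> "InstrumentResponse":
        return cls(
            grid=np.asarray(grid, dtype=float),
            histogram=np.asarray(histogram, dtype=float),
            repetition_period=repetition_period,
        )


def evaluate_decay(model: DecayModel, times: np.ndarray) -> np.ndarray:
    """Evaluate ``sum_i A_i exp(-t/tau_i)`` (scale and background excluded).

    ``times`` must be non-negative, in ns.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    out = np.zeros_like(t)
    for c in model.components:
        out += c.amplitude * np.exp(-t / c.lifetime)
    return out


def normalize_amplitudes(raw: Sequence[float]) -> np.ndarray:
    """Scale non-negative raw amplitudes into A-factors summing to 1."""
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise ValueError("empty amplitude array")
    if np.any(arr < 0):
        raise ValueError("raw amplitudes must be >= 0")
    total = arr.sum()
    if total <= 0:
        raise ValueError("degenerate input: all amplitudes are zero")
    return arr / total


def amplitude_weighted_lifetime(model: DecayModel) -> float:
    """Mean lifetime ``sum_i A_i tau_i`` in ns.

    Proportional to the time-integrated (steady-state) emission of the
    model at fixed radiative rate, hence a proxy for relative
    steady-state brightness between conditions.
    """
    return float(np.dot(model.amplitudes, model.lifetimes))


# ---------------------------------------------------------------------------
# IRF reconvolution

def _emg_cdf(x: np.ndarray, mu: float, sigma: float, tau: float) -> np.ndarray:
    """CDF of an exponential (mean tau) + Gaussian(mu, sigma) sum.

    Stable for all argument regimes via erfcx; avoids the overflowing
    exp * erfc product of the textbook expression.
    """
    u = (x - mu) / sigma
    v = sigma / tau - u
    out = ndtr(u).astype(float)
    # subtractive term exp(-lambda (x-mu) + lambda^2 sigma^2 / 2) * Phi(u - sigma/tau)
    pos = v >= 0
    term = np.empty_like(out)
    if np.any(pos):
        term[pos] = 0.5 * np.exp(-0.5 * u[pos] ** 2) * erfcx(v[pos] / np.sqrt(2.0))
    if np.any(~pos):
        vn = v[~pos]
        un = u[~pos]
        term[~pos] = np.exp(0.5 * vn**2 - 0.5 * un**2) * ndtr(-vn)
    return out - term


def _gaussian_channel_weights(
    edges: np.ndarray,
    mu: float,
    sigma: float,
    lifetimes: np.ndarray,
    period: float,
) -> np.ndarray:
    """Per-channel signal mass for each component under a Gaussian IRF.

    Returns array (n_components, n_channels) of the un-normalised
    photon mass per channel: ``tau_i * [F_i(b) - F_i(a)]`` for the
    reference pulse, plus the summed tails of all preceding pulses.
    One period after excitation the Gaussian is fully integrated, so
    the wrapped contribution is a pure exponential and the pulse-train
    sum is geometric:

        sum_{k>=1} [F(x + kT) - F(a + kT)]
            = C (e^{-a/tau} - e^{-x/tau}) e^{-T/tau} / (1 - e^{-T/tau}),
        C = exp(sigma^2 / (2 tau^2) + mu / tau),

    valid when T - mu >> sigma (checked).  Keeping the tail analytic
    (rather than truncating a sum at a tau-dependent k) makes the
    expectation smooth in tau, which the least-squares fitter relies on.
    """
    if period - mu < 10.0 * sigma:
        raise InvalidModelError(
            "repetition period too close to the IRF centre for wrap-around"
        )
    weights = np.zeros((len(lifetimes), len(edges) - 1))
    for i, tau in enumerate(lifetimes):
        cdf = _emg_cdf(edges, mu, sigma, tau)
        # log of C * e^{-x/tau} * e^{-T/tau} / (1 - e^{-T/tau}) per edge
        log_tail = (
            0.5 * (sigma / tau) ** 2
            + (mu - edges - period) / tau
            - np.log1p(-np.exp(-period / tau))
        )
        acc = cdf - np.exp(np.clip(log_tail, -745.0, 50.0))
        weights[i] = tau * np.diff(acc)
    return weights


def _exp_channel_integrals(
    n_channels: int, dt: float, lifetimes: np.ndarray
) -> np.ndarray:
    """Channel integrals of the periodic exponential decay train.

    For each component, integral over channel k of
    ``exp(-t/tau) / (1 - exp(-T/tau))`` with T = n_channels * dt, the
    steady-state signal under an infinite pulse train.  Shape
    (n_components, n_channels); each row sums to tau_i.
    """
    k = np.arange(n_channels)
    out = np.empty((len(lifetimes), n_channels))
    for i, tau in enumerate(lifetimes):
        e = np.exp(-k * dt / tau)
        out[i] = tau * e * (1.0 - np.exp(-dt / tau)) / (1.0 - np.exp(-n_channels * dt / tau))
    return out


class ConvolutionEngine:
    """Precomputed reconvolution on a fixed uniform time grid.

    Built once per (grid, IRF) pair; ``expected_counts`` is then cheap
    to call repeatedly with varying model parameters, which is what the
    iterative-reconvolution fitter needs.
    """

    def __init__(self, grid: np.ndarray, irf: InstrumentResponse):
        grid = np.asarray(grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("time grid must be 1-D with >= 2 channels")
        steps = np.diff(grid)
        dt = steps.mean()
        if np.any(np.abs(steps - dt) > 1e-6 * dt):
            raise ValueError("time grid must be uniform")
        self.grid = grid
        self.dt = float(dt)
        self.edges = np.concatenate([grid - dt / 2.0, [grid[-1] + dt / 2.0]])
        self.irf = irf
        self.n_window = grid.size
        self.period = irf.repetition_period

        if irf.is_gaussian:
            self._mode = "gaussian"
        else:
            self._mode = "histogram"
            # extended circular grid spanning one repetition period
            n_per = max(self.n_window, int(round(self.period / self.dt)))
            self.n_period = n_per
            irf_grid = np.asarray(irf.grid, dtype=float)
            hist = np.asarray(irf.histogram, dtype=float)
            ext = np.zeros(n_per)
            idx = np.round((irf_grid - grid[0]) / self.dt).astype(int)
            if np.any(np.abs(irf_grid - (grid[0] + idx * self.dt)) > 1e-6 * self.dt):
                raise ValueError("IRF histogram grid does not align with the time grid")
            idx = np.mod(idx, n_per)
            np.add.at(ext, idx, hist)
            ext /= ext.sum()
            self._irf_spectrum = np.fft.rfft(ext)
            self._freqs = np.fft.rfftfreq(n_per, d=self.dt)

    def signal_shape(
        self,
        amplitudes: np.ndarray,
        lifetimes: np.ndarray,
        irf_shift: float = 0.0,
    ) -> np.ndarray:
        """Convolved decay shape on the window, normalised to unit sum."""
        amplitudes = np.asarray(amplitudes, dtype=float)
        lifetimes = np.asarray(lifetimes, dtype=float)
        if self._mode == "gaussian":
            w = _gaussian_channel_weights(
                self.edges,
                self.irf.center + irf_shift,
                self.irf.sigma,
                lifetimes,
                self.period,
            )
            shape = amplitudes @ w
        else:
            d = _exp_channel_integrals(self.n_period, self.dt, lifetimes)
            spec = np.fft.rfft(amplitudes @ d)
            spec *= self._irf_spectrum
            if irf_shift != 0.0:
                spec *= np.exp(-2j * np.pi * self._freqs * irf_shift)
            shape = np.fft.irfft(spec, n=self.n_period)[: self.n_window]
        shape = np.clip(shape, 0.0, None)
        total = shape.sum()
        if total <= 0:
            raise InvalidModelError("decay has no signal mass inside the window")
        return shape / total

    def expected_counts(
        self,
        amplitudes: np.ndarray,
        lifetimes: np.ndarray,
        scale: float,
        background: float,
        irf_shift: float = 0.0,
    ) -> np.ndarray:
        """Expected counts per channel: scale * shape + background."""
        if scale == 0.0:
            return np.full(self.n_window, float(background))
        return scale * self.signal_shape(amplitudes, lifetimes, irf_shift) + background


def convolve_irf(
    model: DecayModel,
    irf: InstrumentResponse,
    grid: np.ndarray,
    irf_shift: float = 0.0,
) -> np.ndarray:
    """Expected TCSPC counts per channel for a decay model and IRF.

    ``grid`` holds uniform channel centres (ns).  The convolution is
    periodic over ``irf.repetition_period`` so that emission excited by
    earlier laser pulses wraps into the window.  The signal portion is
    normalised so that ``sum(counts) - n*background == model.scale``
    exactly (``scale`` is defined as expected in-window signal photons).
    """
    engine = ConvolutionEngine(grid, irf)
    return engine.expected_counts(
        model.amplitudes, model.lifetimes, model.scale, model.background, irf_shift
    )
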
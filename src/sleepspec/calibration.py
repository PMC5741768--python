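"""Amplifier frequency-response calibration.

Different EEG amplifiers attenuate different frequencies differently, so the
same physiological signal yields different spectra on different machines.
The correction is empirical: sinusoids of known amplitude (40 and 355 uV)
are fed into the amplifier at a grid of frequencies, the digitally recorded
amplitude is measured, and the ratio measured/generated at each frequency is
the device's *amplitude reduction rate*.  Rates from the two amplitude runs
are averaged per frequency and a natural cubic spline interpolates between
grid frequencies.  Power spectra are corrected by dividing each bin by the
squared rate at that bin's frequency (power scales with amplitude squared).

The amplitude of the recorded sinusoid is estimated by a least-squares fit
of a sinusoid at the known frequency (amplitude and phase free), which is
leakage-free for calibration frequencies that do not land on an FFT bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .exceptions import ChannelLookupError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Calibration sweep frequency grid (Hz): 0.05, then every 0.1 Hz from
#: 0.1-2, every 1 Hz from 2-20 and every 10 Hz from 10-100 (union of the
#: overlapping segments, sorted and deduplicated).
CAL_GRID = np.unique(np.round(np.concatenate([
    [0.05],
    np.arange(0.1, 2.0 + 1e-9, 0.1),
    np.arange(2.0, 20.0 + 1e-9, 1.0),
    np.arange(10.0, 100.0 + 1e-9, 10.0),
]), 4))

#: Generated calibration amplitudes, microvolts.
CAL_AMPLITUDES = (40.0, 355.0)


@dataclass
class SweepEntry:
    frequency: float
    generated_amplitude: float
    recorded_signal: np.ndarray
    fs: float


@dataclass
class CalibrationSweep:
    """All recorded calibration runs for one device."""

    device_id: str
    entries: list[SweepEntry] = field(default_factory=list)


@dataclass
class CalibrationCurve:
    """Per-device amplitude-reduction rate as a function of frequency."""

    device_id: str
    grid_freqs: np.ndarray
    rates: np.ndarray
    _spline: CubicSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.grid_freqs = np.asarray(self.grid_freqs, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.grid_freqs) < 2:
            raise ValidationError("calibration curve needs at least two grid points")
        if np.any(np.diff(self.grid_freqs) <= 0):
            raise ValidationError("calibration grid frequencies must be increasing")
        if np.any(self.rates <= 0):
            raise ValidationError("amplitude reduction rates must be positive")
        self._spline = CubicSpline(self.grid_freqs, self.rates, bc_type="natural")

    def __call__(self, freqs: np.ndarray | float) -> np.ndarray:
        """Interpolated rate; exact at grid points."""
        r = self._spline(np.asarray(freqs, dtype=float))
        if np.any(r <= 0):
            raise ValidationError(
                f"interpolated rate non-positive for device {self.device_id}"
            )
        return r


def measure_amplitude(signal: np.ndarray, fs: float, frequency: float) -> float:
    """Least-squares amplitude of the sinusoidal component at ``frequency``.

    Fits a*cos + b*sin + intercept and returns hypot(a, b), the peak
    amplitude in the signal's own units.  Requires at least 10 cycles of
    the target frequency, relaxed to 4 s of data below 2.5 Hz (where 10
    cycles would demand very long runs).
    """
    signal = np.asarray(signal, dtype=float)
    duration = len(signal) / fs
    need = 10.0 / frequency if frequency >= 2.5 else 4.0
    if duration < need - 1e-9:
        raise ValidationError(
            f"signal too short for {frequency} Hz: {duration:.2f} s < {need:.2f} s"
        )
    t = np.arange(len(signal)) / fs
    design = np.column_stack([
        np.cos(2 * np.pi * frequency * t),
        np.sin(2 * np.pi * frequency * t),
        np.ones_like(t),
    ])
    coef, *_ = np.linalg.lstsq(design, signal, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


def estimate_reduction_rate(sweep: CalibrationSweep) -> dict[float, float]:
    """Per-frequency amplitude-reduction rate, averaged over amplitude runs.

    rate(f) = mean over runs of measured/generated amplitude.  A frequency
    covered by only one amplitude run is accepted with a warning.  Rates
    outside (0, 2] indicate an implausible device and raise.
    """
    by_freq: dict[float, list[float]] = {}
    for e in sweep.entries:
        measured = measure_amplitude(e.recorded_signal, e.fs, e.frequency)
        by_freq.setdefault(round(e.frequency, 4), []).append(
            measured / e.generated_amplitude
        )
    rates = {}
    for f, runs in sorted(by_freq.items()):
        if len(runs) < 2:
            logger.warning("device %s: single amplitude run at %g Hz",
                           sweep.device_id, f)
        rate = float(np.mean(runs))
        if rate <= 0 or rate > 2:
            raise ValidationError(
                f"device {sweep.device_id}: implausible rate {rate:.3g} at {f} Hz"
            )
        rates[f] = rate
    return rates


def build_curve(rates: dict[float, float], device_id: str = "unknown") -> CalibrationCurve:
    """Natural cubic spline through the per-frequency rates."""
    freqs = np.array(sorted(rates))
    return CalibrationCurve(device_id=device_id, grid_freqs=freqs,
                            rates=np.array([rates[f] for f in freqs]))


def correct_psd(psd: np.ndarray, freqs: np.ndarray, curve: CalibrationCurve) -> np.ndarray:
    """Divide each PSD bin by the squared reduction rate at its frequency."""
    rate = curve(freqs)
    return np.asarray(psd, dtype=float) / rate ** 2


def apply_response(psd: np.ndarray, freqs: np.ndarray, curve: CalibrationCurve) -> np.ndarray:
    """Inverse of correct_psd: simulate what the device would record."""
    rate = curve(freqs)
    return np.asarray(psd, dtype=float) * rate ** 2


# --------------------------------------------------------------------------
# Curve file I/O
# --------------------------------------------------------------------------

def write_curves(curves: dict[str, CalibrationCurve], path: str | Path) -> None:
    rows = []
    for dev, c in curves.items():
        for f, r in zip(c.grid_freqs, c.rates):
            rows.append({"device_id": dev, "frequency_hz": f, "rate": r})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_curves(path: str | Path) -> dict[str, CalibrationCurve]:
    df = pd.read_csv(path, dtype={"device_id": str})
    if not {"device_id", "frequency_hz", "rate"}.issubset(df.columns):
        raise FormatError(f"{path}: expected device_id, frequency_hz, rate columns")
    curves = {}
    for dev, g in df.groupby("device_id"):
        g = g.sort_values("frequency_hz")
        curves[dev] = CalibrationCurve(device_id=str(dev),
                                       grid_freqs=g["frequency_hz"].to_numpy(),
                                       rates=g["rate"].to_numpy())
    return curves


def curve_for_device(curves: dict[str, CalibrationCurve], device_id: str) -> CalibrationCurve:
    try:
        return curves[device_id]
    except KeyError:
        raise ChannelLookupError(
            f"no calibration curve for device {device_id!r}; "
            f"available: {sorted(curves)}"
        ) from None
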
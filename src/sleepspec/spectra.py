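"""State-specific window selection and relative log-power spectra.

NREM spectra pool stage-2 and slow-wave sleep epochs; REM spectra use REM
epochs.  Within each eligible 20 s epoch, 4 s Hann-tapered analysis windows
are laid at 2 s steps inside maximal runs of artifact-free 4 s segments;
windows never span a stage change or an artifact segment.  Per-window
one-sided periodogram densities (0.25 Hz bins) are averaged, the device
frequency response is divided out, and power in 1-40 Hz is expressed as
relative log10 power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window

from .calibration import CalibrationCurve, correct_psd
from .exceptions import ProcessingError, ValidationError
from .io import (EPOCH_SEC, FREQ_BINS, N_BINS, SEGMENT_SEC, SEGMENTS_PER_EPOCH,
                 STAGES, STATE_STAGES, ArtifactMask, Hypnogram, Recording)

logger = logging.getLogger(__name__)

WINDOW_SEC = 4.0
STEP_SEC = 2.0


@dataclass
class WindowPlan:
    """Start times (seconds) of the eligible 4 s analysis windows."""

    state: str
    window_starts: np.ndarray  # seconds from recording start
    source_epochs: np.ndarray  # epoch index of each window

    def __len__(self) -> int:
        return len(self.window_starts)


@dataclass
class MacroSummary:
    """Sleep macrostructure: per-stage minutes and % of total sleep time."""

    minutes: dict[str, float]
    percent: dict[str, float]  # over sleep stages only; NaN when TST == 0
    total_sleep_min: float


def plan_windows(hypnogram: Hypnogram, mask: ArtifactMask, state: str) -> WindowPlan:
    """Enumerate 4 s windows at 2 s steps inside clean, state-matching runs.

    The artifact mask has five 4 s segments per 20 s epoch.  Within each
    epoch of the requested state, every maximal run of k contiguous
    artifact-free segments contributes 2k-1 windows.  Windows do not bridge
    epochs, so a single clean epoch yields at most 9 windows.
    """
    if state not in STATE_STAGES:
        raise ValidationError(f"state must be one of {sorted(STATE_STAGES)}")
    wanted = STATE_STAGES[state]
    n_epochs = len(hypnogram)
    if len(mask) < n_epochs * SEGMENTS_PER_EPOCH:
        raise ValidationError(
            f"artifact mask covers {len(mask)} segments, hypnogram needs "
            f"{n_epochs * SEGMENTS_PER_EPOCH}"
        )
    starts, epochs = [], []
    for ep, stage in enumerate(hypnogram.stages):
        if stage not in wanted:
            continue
        seg0 = ep * SEGMENTS_PER_EPOCH
        clean = ~mask.flags[seg0:seg0 + SEGMENTS_PER_EPOCH]
        # maximal runs of contiguous clean segments within this epoch
        i = 0
        while i < SEGMENTS_PER_EPOCH:
            if not clean[i]:
                i += 1
                continue
            j = i
            while j < SEGMENTS_PER_EPOCH and clean[j]:
                j += 1
            run_start = ep * EPOCH_SEC + i * SEGMENT_SEC
            run_len = (j - i) * SEGMENT_SEC
            t = 0.0
            while t + WINDOW_SEC <= run_len + 1e-9:
                starts.append(run_start + t)
                epochs.append(ep)
                t += STEP_SEC
            i = j
    if not starts:
        logger.warning("no eligible %s windows found", state)
    return WindowPlan(state=state,
                      window_starts=np.array(starts, dtype=float),
                      source_epochs=np.array(epochs, dtype=int))


def compute_psd(recording: Recording, plan: WindowPlan,
                curve: CalibrationCurve | None = None) -> np.ndarray:
    """Average Hann-tapered periodogram density on the 157-bin 1-40 Hz grid.

    Returns an array of shape (n_channels, 157) in uV^2/Hz (arbitrary after
    calibration correction; absolute scale cancels in relative power).
    Each window is demeaned before tapering to keep DC leakage out of the
    lowest bins.  The 4 s window length gives exactly 0.25 Hz resolution,
    so 1-40 Hz maps onto FFT bins 4..160 with no interpolation.

    Parameters
    ----------
    curve
        Optional device calibration curve; when given, each PSD bin is
        divided by the squared amplitude-reduction rate at that frequency.
    """
    fs = recording.fs
    nwin = fs * WINDOW_SEC
    if abs(nwin - round(nwin)) > 1e-9:
        raise ValidationError(f"fs={fs} gives a non-integer 4 s window length")
    nwin = int(round(nwin))
    if len(plan) == 0:
        raise ProcessingError(
            f"empty window plan for subject {recording.subject_id!r}, "
            f"state {plan.state}"
        )
    df = fs / nwin  # 0.25 Hz by construction
    if abs(df - 0.25) > 1e-9:
        raise ValidationError(
            f"native resolution {df} Hz != 0.25 Hz; resample or choose fs with "
            f"4 s windows of 0.25 Hz resolution"
        )
    taper = get_window("hann", nwin)
    scale = 2.0 / (fs * np.sum(taper ** 2))  # one-sided Welch density scaling
    k = np.round(FREQ_BINS / df).astype(int)  # 4..160

    starts = np.round(plan.window_starts * fs).astype(int)
    if starts.max() + nwin > recording.n_samples:
        raise ValidationError("window plan extends past the end of the recording")
    psd = np.zeros((len(recording.channels), N_BINS))
    # gather all windows at once: (n_windows, nwin)
    idx = starts[:, None] + np.arange(nwin)[None, :]
    for ci in range(len(recording.channels)):
        seg = recording.data[ci][idx]
        seg = seg - seg.mean(axis=1, keepdims=True)
        spec = np.fft.rfft(seg * taper, axis=1)
        per = scale * np.abs(spec) ** 2
        psd[ci] = per.mean(axis=0)[k]
    if curve is not None:
        psd = correct_psd(psd, FREQ_BINS, curve)
    return psd


def relative_log_power(psd: np.ndarray, eps: float | None = None) -> np.ndarray:
    """log10 of each bin's share of total 1-40 Hz power.

    Accepts a (157,) vector or (n_channels, 157) matrix.  Zero bins are
    floored at ``eps`` (default: 1e-12 x the row maximum) with a warning,
    since the logarithm is otherwise undefined.  Output antilogs sum to 1
    per row by construction; the result is invariant to rescaling the input.
    """
    orig_1d = np.asarray(psd).ndim == 1
    psd = np.atleast_2d(np.asarray(psd, dtype=float)).copy()
    if np.any(psd < 0):
        raise ValidationError("PSD must be non-negative")
    rowmax = psd.max(axis=1, keepdims=True)
    if np.any(rowmax <= 0):
        raise ValidationError("PSD is identically zero on at least one channel")
    if np.any(psd == 0):
        floor = eps if eps is not None else 1e-12
        logger.warning("zero PSD bins floored at %g x row maximum", floor)
        psd = np.maximum(psd, floor * rowmax)
    rel = psd / psd.sum(axis=1, keepdims=True)
    out = np.log10(rel)
    return out[0] if orig_1d else out


def macrostructure(hypnogram: Hypnogram) -> MacroSummary:
    """Stage tallies: minutes per stage and percentage of total sleep time.

    Total sleep time counts N1, N2, SWS and REM epochs.  With zero sleep
    the percentages are undefined and reported as NaN.
    """
    if len(hypnogram) == 0:
        raise ValidationError("empty hypnogram")
    epoch_min = EPOCH_SEC / 60.0
    minutes = {s: hypnogram.stages.count(s) * epoch_min for s in STAGES}
    sleep_stages = ("N1", "N2", "SWS", "REM")
    tst = sum(minutes[s] for s in sleep_stages)
    if tst > 0:
        percent = {s: 100.0 * minutes[s] / tst for s in sleep_stages}
    else:
        logger.warning("total sleep time is zero; stage percentages undefined")
        percent = {s: float("nan") for s in sleep_stages}
    return MacroSummary(minutes=minutes, percent=percent, total_sleep_min=tst)
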
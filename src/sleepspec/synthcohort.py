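"""Synthetic cohorts with known ground truth.

No public dataset accompanies this kind of retrospective sleep-EEG study,
so every pipeline stage is exercised on simulated cohorts whose generative
structure is fully known.  Relative log-power spectra are generated
directly in log10 space: a realistic mean spectral profile per state, a
linear age trend, plus a zero-mean Gaussian field that is smooth across
both electrodes (exponential spatial kernel on 10-20 head positions) and
frequency bins (exponential kernel on |delta f|), sharing a latent trait
factor at planted cells so that the model-implied age-partial correlation
between trait and power equals the requested rho exactly.  Each subject's
spectrum is then renormalized so antilogs sum to one.

The default cohort mirrors the study design this package targets: 68
females and 83 males aged 17-69, an age-declining trait, 18 electrodes
with a handful of electrode failures, and female-only planted effects
(negative REM delta/theta, positive REM beta, positive NREM alpha/sigma)
with males null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CAL_AMPLITUDES, CAL_GRID, CalibrationSweep, SweepEntry
from .exceptions import ValidationError
from .io import (FREQ_BINS, N_BINS, SEGMENTS_PER_EPOCH, STATE_STAGES,
                 ArtifactMask, Hypnogram, Recording, SpectraTable)
from .montage import MONTAGE18, electrode_distance_matrix


# --------------------------------------------------------------------------
# Cohort specification
# --------------------------------------------------------------------------

@dataclass
class PlantedEffect:
    """A sex-specific band of true age-partial correlation with the trait."""

    state: str
    f_lo: float
    f_hi: float
    electrodes: list[str]
    sex: str  # 'F' or 'M'
    rho: float


def default_effects() -> list[PlantedEffect]:
    """Female-only effects emulating the published topography; males null."""
    return [
        PlantedEffect("REM", 2.25, 5.25,
                      ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"], "F", -0.45),
        PlantedEffect("REM", 12.25, 19.5,
                      ["F3", "Fz", "F4", "C3", "Cz", "C4"], "F", 0.45),
        PlantedEffect("NREM", 8.0, 15.0,
                      ["C3", "Cz", "C4", "T5", "P3", "P4", "O1", "O2"], "F", 0.45),
    ]


#: Electrode-failure counts emulating a realistic multi-device cohort
#: (26 failures spread over ~21 subjects, frontopolar sites worst).
DEFAULT_FAILURES = {"Fp1": 10, "Fp2": 3, "F4": 2, "F8": 2, "F7": 2, "T5": 2,
                    "F3": 1, "T3": 1, "C3": 1, "O2": 1, "T6": 1}


@dataclass
class CohortSpec:
    n_female: int = 68
    n_male: int = 83
    age_range: tuple[float, float] = (17.0, 69.0)
    electrodes: list[str] = field(default_factory=lambda: list(MONTAGE18))
    states: tuple[str, ...] = ("NREM", "REM")
    planted: list[PlantedEffect] = field(default_factory=default_effects)
    age_slope_trait: float = -0.35   # trait SD units per age SD
    age_slope_power: float = 0.15    # log10 units per age SD at the band extremes
    noise_sd: float = 0.15           # cell SD in log10 units
    spatial_scale: float = 1.5       # head radii; exp(-d/scale) spatial corr
    spectral_scale: float = 5.0      # Hz; exp(-|df|/scale) bin-to-bin corr
    electrode_failures: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FAILURES))
    seed: int = 0

    def validate(self) -> None:
        if self.n_female < 5 or self.n_male < 5:
            raise ValidationError("need at least 5 subjects per sex")
        if abs(self.age_slope_trait) >= 1:
            raise ValidationError("|age_slope_trait| must be < 1 (SD units)")
        for eff in self.planted:
            if not (abs(eff.rho) < 1):
                raise ValidationError(f"|rho| must be < 1, got {eff.rho}")
            if not (1.0 <= eff.f_lo <= eff.f_hi <= 40.0):
                raise ValidationError(f"band {eff.f_lo}-{eff.f_hi} outside 1-40 Hz")
            if eff.state not in STATE_STAGES:
                raise ValidationError(f"unknown state {eff.state!r}")
            if eff.sex not in ("F", "M"):
                raise ValidationError(f"sex must be F or M, got {eff.sex!r}")
            bad = [e for e in eff.electrodes if e not in self.electrodes]
            if bad:
                raise ValidationError(f"planted electrodes not in montage: {bad}")


@dataclass
class GroundTruth:
    trait_z: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    #: (state, sex) -> (E, 157) achieved first-order trait loadings: the
    #: planted rho on planted cells plus the mechanical complement the
    #: relative-power constraint forces on the remaining bins.
    rho_maps: dict[tuple[str, str], np.ndarray]
    effects: list[PlantedEffect]


# --------------------------------------------------------------------------
# Mean spectral profiles
# --------------------------------------------------------------------------

def _base_log_profile(state: str) -> np.ndarray:
    """Typical relative log10 power profile on the 157-bin grid.

    A power-law decay with a sleep-spindle (sigma) bump in NREM and a
    flatter high-frequency tail in REM; normalized so antilogs sum to 1.
    """
    f = FREQ_BINS
    if state == "NREM":
        v = -2.3 * np.log10(f) + 0.5 * np.exp(-0.5 * ((f - 13.5) / 1.3) ** 2)
    else:
        v = -2.0 * np.log10(f) + 0.15 * np.exp(-0.5 * ((f - 6.0) / 2.0) ** 2)
    v = v - np.log10(np.sum(10.0 ** v))
    return v


def _age_profile(f: np.ndarray, scale: float) -> np.ndarray:
    """Smooth age slope over frequency: slight low-frequency gain, high-
    frequency loss with advancing age (log10 units per age SD)."""
    return scale * (0.5 - 1.0 / (1.0 + np.exp(-(f - 11.0) / 2.0)))


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def _smooth_chol(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    d = electrode_distance_matrix(spec.electrodes)
    cov_s = np.exp(-d / spec.spatial_scale)
    df = np.abs(FREQ_BINS[:, None] - FREQ_BINS[None, :])
    cov_f = np.exp(-df / spec.spectral_scale)
    jitter = 1e-10
    ls = np.linalg.cholesky(cov_s + jitter * np.eye(len(cov_s)))
    lf = np.linalg.cholesky(cov_f + jitter * np.eye(N_BINS))
    return ls, lf


def _achievable_loading(rho: np.ndarray, w: np.ndarray) -> np.ndarray:
    """First-order-achievable trait loadings on the relative-power simplex.

    Because antilogs sum to one, log relative power weighted by the base
    power shares ``w`` is constant to first order: no loading pattern with
    a nonzero w-weighted mean can survive renormalization.  A planted band
    correlation therefore mechanically forces a complement of opposite
    sign elsewhere.  This returns the planted loadings unchanged on their
    cells and spreads the exact complement uniformly over the remaining
    bins of the same electrode, which renormalization then preserves.
    """
    lam = rho.copy()
    for ei in range(rho.shape[0]):
        band = rho[ei] != 0
        if not band.any():
            continue
        w_band = w[band].sum()
        a0 = float(w @ rho[ei])
        off = -a0 / (1.0 - w_band)
        if abs(off) >= 1:
            raise ValidationError("planted band too heavy for its rho; "
                                  "mechanical complement would exceed |1|")
        lam[ei, ~band] = off
    return lam


def _power_preserving_operator(spec: CohortSpec, w: np.ndarray,
                               n_iter: int = 8) -> np.ndarray:
    """Linear map making a unit-variance smooth spectral field power-
    preserving: (approximately) zero w-weighted mean and unit per-bin
    variance.  Alternates exact projection with exact per-bin rescaling,
    propagating the field covariance analytically."""
    b = len(w)
    df = np.abs(FREQ_BINS[:, None] - FREQ_BINS[None, :])
    cov = np.exp(-df / spec.spectral_scale)
    proj = np.eye(b) - np.outer(np.ones(b), w)
    op = np.eye(b)
    for _ in range(n_iter):
        cov = proj @ cov @ proj.T
        d = 1.0 / np.sqrt(np.maximum(np.diag(cov), 1e-12))
        cov = cov * np.outer(d, d)
        op = (proj * d[:, None]) @ op
    return op


def _rho_map(spec: CohortSpec, state: str, sex: str) -> np.ndarray:
    rho = np.zeros((len(spec.electrodes), N_BINS))
    e_idx = {e: i for i, e in enumerate(spec.electrodes)}
    for eff in spec.planted:
        if eff.state != state or eff.sex != sex:
            continue
        bins = (FREQ_BINS >= eff.f_lo - 1e-9) & (FREQ_BINS <= eff.f_hi + 1e-9)
        for e in eff.electrodes:
            rho[e_idx[e], bins] = eff.rho  # later effects take precedence
    return rho


def generate_cohort(spec: CohortSpec, seed: int | None = None
                    ) -> tuple[dict[str, SpectraTable], pd.DataFrame,
                               pd.DataFrame, GroundTruth]:
    """Generate spectra (per state), subject table, RES table, ground truth.

    Reproducible from the seed (``seed`` overrides ``spec.seed``).  The
    model-implied age-partial correlation between trait and power equals
    the planted rho at planted cells and zero elsewhere; the per-subject
    renormalization of relative power perturbs this only marginally.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_female + spec.n_male
    sex = np.array(["F"] * spec.n_female + ["M"] * spec.n_male)
    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, size=n)
    age_z = (age - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))
    g = rng.standard_normal(n)
    s = spec.age_slope_trait
    trait_z = s * age_z + np.sqrt(1 - s ** 2) * g

    ls, lf = _smooth_chol(spec)
    beta_age = _age_profile(FREQ_BINS, spec.age_slope_power)
    spectra: dict[str, SpectraTable] = {}
    rho_maps: dict[tuple[str, str], np.ndarray] = {}
    subject_ids = [f"s{i + 1:03d}" for i in range(n)]

    # assign electrode failures to random subjects (reproducible)
    fail = np.zeros((n, len(spec.electrodes)), dtype=bool)
    e_idx = {e: i for i, e in enumerate(spec.electrodes)}
    for ch, count in spec.electrode_failures.items():
        if ch not in e_idx:
            continue
        for si in rng.choice(n, size=count, replace=False):
            fail[si, e_idx[ch]] = True

    for state in spec.states:
        base = _base_log_profile(state)
        w = 10.0 ** base  # base power shares; sums to 1 by construction
        lam_f = _achievable_loading(_rho_map(spec, state, "F"), w)
        lam_m = _achievable_loading(_rho_map(spec, state, "M"), w)
        rho_maps[(state, "F")] = lam_f
        rho_maps[(state, "M")] = lam_m
        lam = np.where((sex == "F")[:, None, None], lam_f[None], lam_m[None])
        eps = rng.standard_normal((n, len(spec.electrodes), N_BINS))
        smooth = np.einsum("ij,njk,lk->nil", ls, eps, lf, optimize=True)
        # constrain the noise field to preserve total power to first order
        # (zero w-weighted mean per electrode) while keeping unit marginal
        # variance per bin, so renormalization barely perturbs the planted
        # correlation structure.  Alternating projection and rescaling,
        # tracked analytically on the spectral covariance, converges to an
        # operator with both properties.
        smooth = smooth @ _power_preserving_operator(spec, w).T
        v = (base[None, None, :]
             + beta_age[None, None, :] * age_z[:, None, None]
             + spec.noise_sd * (lam * g[:, None, None]
                                + np.sqrt(1.0 - lam ** 2) * smooth))
        # renormalize: antilogs sum to 1 per subject x electrode
        v = v - np.log10(np.sum(10.0 ** v, axis=2, keepdims=True))
        v[fail] = np.nan
        spectra[state] = SpectraTable(state=state, subjects=list(subject_ids),
                                      electrodes=list(spec.electrodes), values=v)

    res = 22.0 + 6.0 * trait_z
    subjects = pd.DataFrame({
        "subject_id": subject_ids,
        "sex": sex,
        "age": np.round(age, 1),
        "raven_raw": np.clip(np.round(res), 0, 36).astype(int),
        "cft_raw": np.nan,
        "device_id": "dev01",
    })
    res_table = pd.DataFrame({"subject_id": subject_ids, "res": res,
                              "provenance": "APM_only"})
    truth = GroundTruth(trait_z=trait_z, age=age, sex=sex, rho_maps=rho_maps,
                        effects=list(spec.planted))
    return spectra, subjects, res_table, truth


def null_spec(n_female: int = 30, n_male: int = 30,
              electrodes: list[str] | None = None,
              states: tuple[str, ...] = ("REM",), seed: int = 0) -> CohortSpec:
    """A cohort spec with no planted effects and no electrode failures."""
    return CohortSpec(n_female=n_female, n_male=n_male,
                      electrodes=list(electrodes) if electrodes else list(MONTAGE18),
                      states=states, planted=[], electrode_failures={}, seed=seed)


# --------------------------------------------------------------------------
# Raw-signal fixtures
# --------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator, amp: float) -> np.ndarray:
    """Gaussian 1/f noise via spectral shaping, RMS ~ amp."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec = spec / np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return amp * x / x.std()


def generate_signal_fixture(stage_plan: list[str],
                            components: list[tuple[float, float, str]],
                            fs: float = 250.0, seed: int = 0,
                            channels: tuple[str, ...] = ("C3", "C4"),
                            noise_amp: float = 5.0,
                            subject_id: str = "sim01",
                            device_id: str = "dev01"
                            ) -> tuple[Recording, Hypnogram, ArtifactMask]:
    """Sinusoids-plus-pink-noise recording with a known stage plan.

    ``components`` is a list of (frequency Hz, peak amplitude uV, state);
    each sinusoid is active only during epochs of its state (pooled NREM /
    REM, or a raw stage code).  The artifact mask comes back all-clear so
    tests can flag segments themselves.
    """
    hyp = Hypnogram(list(stage_plan))
    n = int(round(len(stage_plan) * 20.0 * fs))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    epoch_of_sample = (np.arange(n) / fs / 20.0).astype(int)
    stage_arr = np.array(stage_plan)[epoch_of_sample]
    data = np.empty((len(channels), n))
    for ci in range(len(channels)):
        x = _pink_noise(n, rng, noise_amp)
        for freq, amp, state in components:
            if freq >= fs / 2:
                raise ValidationError(f"component at {freq} Hz >= Nyquist")
            stages = STATE_STAGES.get(state, {state})
            active = np.isin(stage_arr, list(stages))
            x = x + amp * np.sin(2 * np.pi * freq * t) * active
        data[ci] = x
    rec = Recording(subject_id=subject_id, channels=list(channels), fs=fs,
                    data=data, device_id=device_id)
    mask = ArtifactMask(np.zeros(len(stage_plan) * SEGMENTS_PER_EPOCH, dtype=bool))
    return rec, hyp, mask


# --------------------------------------------------------------------------
# Calibration sweeps
# --------------------------------------------------------------------------

@dataclass
class FirstOrderHighPass:
    """Analytic |H(f)| of a first-order RC high-pass filter."""

    cutoff_hz: float

    def response(self, f: np.ndarray | float) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return 1.0 / np.sqrt(1.0 + (self.cutoff_hz / f) ** 2)


@dataclass
class IdentityFilter:
    def response(self, f: np.ndarray | float) -> np.ndarray:
        return np.ones_like(np.asarray(f, dtype=float))


def generate_calibration_sweep(filter_spec, seed: int = 0,
                               device_id: str = "dev01", fs: float = 250.0,
                               noise_sd: float = 0.2,
                               grid: np.ndarray | None = None
                               ) -> tuple[CalibrationSweep, dict[float, float]]:
    """Simulated sinusoid sweep through a known filter; both 40 and 355 uV
    runs per grid frequency.  Returns the sweep and the analytic ground-
    truth rates at the grid frequencies."""
    rng = np.random.default_rng(seed)
    grid = CAL_GRID if grid is None else np.asarray(grid, dtype=float)
    entries = []
    truth = {}
    for f in grid:
        gain = float(filter_spec.response(f))
        truth[round(float(f), 4)] = gain
        duration = 4.0 if f >= 0.5 else 2.0 / f  # >= 2 cycles below 0.5 Hz
        t = np.arange(int(round(duration * fs))) / fs
        for amp in CAL_AMPLITUDES:
            phase = rng.uniform(0, 2 * np.pi)
            sig = amp * gain * np.sin(2 * np.pi * f * t + phase)
            sig = sig + rng.normal(0, noise_sd, size=len(t))
            entries.append(SweepEntry(frequency=float(f), generated_amplitude=amp,
                                      recorded_signal=sig, fs=fs))
    return CalibrationSweep(device_id=device_id, entries=entries), truth
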
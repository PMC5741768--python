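"""Readers and writers for every external format the pipeline touches.

Raw polysomnography arrives as EDF (read through MNE).  Sleep staging is a
plain-text hypnogram with one stage token per 20 s epoch; artifact rejection
is a plain-text mask with one 0/1 flag per 4 s segment (five segments per
epoch).  Subject metadata is a CSV table.  Spectra are stored as a single
long-format CSV (subject, state, electrode, bin_hz, value) which is portable
and diffable at the data volumes involved.

A minimal EDF *writer* is included so that test fixtures and simulated
recordings can round-trip through the same reader the real data uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ChannelLookupError, FormatError, ValidationError
from .montage import MONTAGE18

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Frequency grid
# --------------------------------------------------------------------------

#: Analysis grid: 1.00-40.00 Hz inclusive at 0.25 Hz resolution -> 157 bins.
FREQ_BINS = np.round(np.arange(1.0, 40.0 + 1e-9, 0.25), 4)
N_BINS = len(FREQ_BINS)
assert N_BINS == 157

EPOCH_SEC = 20.0
SEGMENT_SEC = 4.0
SEGMENTS_PER_EPOCH = 5

#: Sleep-stage codes: wake, NREM stage 1, NREM stage 2, slow-wave sleep,
#: REM, movement/unknown.
STAGES = ("W", "N1", "N2", "SWS", "REM", "MT")

#: Pooled analysis states.
STATE_STAGES = {"NREM": {"N2", "SWS"}, "REM": {"REM"}}


# --------------------------------------------------------------------------
# Domain containers
# --------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel EEG signal in microvolts.

    ``data`` has shape (n_channels, n_samples); channel order matches
    ``channels``.  ``device_id`` keys into calibration curves.
    """

    subject_id: str
    channels: list[str]
    fs: float
    data: np.ndarray
    device_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValidationError("data must be (n_channels, n_samples)")
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError("channel labels must be unique")
        unknown = [c for c in self.channels if c not in MONTAGE18]
        if unknown:
            raise ValidationError(
                f"channel labels outside the 10-20 montage: {unknown}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def get(self, channel: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(channel)]
        except ValueError:
            raise ChannelLookupError(
                f"channel {channel!r} not in recording; available: {self.channels}"
            ) from None


@dataclass
class Hypnogram:
    """One stage code per 20 s epoch."""

    stages: list[str]

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValidationError(f"unknown stage codes: {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return len(self.stages) * EPOCH_SEC


@dataclass
class ArtifactMask:
    """Boolean flag per 4 s segment; True marks an artifact."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1:
            raise ValidationError("artifact mask must be one-dimensional")

    def __len__(self) -> int:
        return len(self.flags)


@dataclass
class SpectraTable:
    """Relative log10 power per subject x electrode x frequency bin.

    ``values`` has shape (n_subjects, n_electrodes, 157); a missing
    electrode for a subject is a row of NaN.  For every non-missing row the
    antilogs sum to 1 (relative power normalisation).
    """

    state: str
    subjects: list[str]
    electrodes: list[str]
    values: np.ndarray
    bins: np.ndarray = field(default_factory=lambda: FREQ_BINS.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.state not in STATE_STAGES:
            raise ValidationError(f"state must be one of {sorted(STATE_STAGES)}")
        if self.values.shape != (len(self.subjects), len(self.electrodes), len(self.bins)):
            raise ValidationError("values shape does not match labels")
        if len(self.bins) != N_BINS or not np.allclose(self.bins, FREQ_BINS):
            raise ValidationError(f"frequency grid must be the {N_BINS}-bin 1-40 Hz grid")

    @property
    def missing(self) -> np.ndarray:
        """(n_subjects, n_electrodes) boolean mask of missing electrodes."""
        return np.isnan(self.values).any(axis=2)

    def validate(self, atol: float = 1e-9) -> None:
        """Check the relative-power normalisation on all non-missing rows."""
        ok = ~self.missing
        if ok.any():
            sums = np.nansum(10.0 ** self.values, axis=2)
            err = np.abs(sums[ok] - 1.0)
            if err.max() > atol:
                raise ValidationError(
                    f"antilog power sums deviate from 1 by up to {err.max():.3g}"
                )

    def subject_index(self, subject_id: str) -> int:
        try:
            return self.subjects.index(subject_id)
        except ValueError:
            raise AlignmentError(
                f"subject {subject_id!r} not present in spectra table"
            ) from None

    def subset_subjects(self, subject_ids: list[str]) -> "SpectraTable":
        idx = [self.subject_index(s) for s in subject_ids]
        return SpectraTable(self.state, list(subject_ids), list(self.electrodes),
                            self.values[idx], self.bins.copy())


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a Recording as a plain (16-bit) EDF file.

    One-second data records; the sampling rate must therefore be a positive
    integer.  Physical units are microvolts.  The subject id goes into the
    patient field and the device id into the recording field.
    """
    path = Path(path)
    fs = recording.fs
    if fs != int(fs) or fs <= 0:
        raise ValidationError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    ns = len(recording.channels)
    n_rec = int(np.ceil(recording.n_samples / fs))
    data = recording.data
    if n_rec * fs != recording.n_samples:  # pad final record with zeros
        pad = n_rec * fs - recording.n_samples
        data = np.pad(data, ((0, 0), (0, pad)))

    def f8(x: float) -> bytes:
        s = f"{x:.8g}"[:8]
        return s.ljust(8).encode("ascii")

    def fstr(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    phys_max = []
    scaled = np.empty_like(data, dtype=np.int16)
    for i in range(ns):
        m = float(np.max(np.abs(data[i]))) or 1.0
        # round the physical limit up so its 8-char header string is exact
        pm = float(f"{m * 1.0001:.6g}")
        while pm < m:
            pm = float(f"{pm * 1.001:.6g}")
        phys_max.append(pm)
        scaled[i] = np.round(data[i] / pm * 32767).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(fstr("0", 8))
        fh.write(fstr(recording.subject_id, 80))
        fh.write(fstr(f"dev={recording.device_id}", 80))
        fh.write(fstr("01.01.00", 8))
        fh.write(fstr("00.00.00", 8))
        fh.write(fstr(str(256 * (1 + ns)), 8))
        fh.write(fstr("", 44))
        fh.write(fstr(str(n_rec), 8))
        fh.write(fstr("1", 8))
        fh.write(fstr(str(ns), 4))
        for ch in recording.channels:
            fh.write(fstr(f"EEG {ch}", 16))
        for _ in range(ns):
            fh.write(fstr("", 80))
        for _ in range(ns):
            fh.write(fstr("uV", 8))
        for pm in phys_max:
            fh.write(f8(-pm))
        for pm in phys_max:
            fh.write(f8(pm))
        for _ in range(ns):
            fh.write(f8(-32768))
        for _ in range(ns):
            fh.write(f8(32767))
        for _ in range(ns):
            fh.write(fstr("", 80))
        for _ in range(ns):
            fh.write(fstr(str(fs), 8))
        for _ in range(ns):
            fh.write(fstr("", 32))
        for r in range(n_rec):
            for i in range(ns):
                fh.write(scaled[i, r * fs:(r + 1) * fs].astype("<i2").tobytes())


def _read_edf_ids(path: Path) -> tuple[str, str]:
    """Pull subject and device ids straight from the EDF header fields."""
    with open(path, "rb") as fh:
        head = fh.read(256)
    if len(head) < 256:
        raise FormatError(f"{path}: EDF header truncated")
    patient = head[8:88].decode("ascii", errors="replace").strip()
    rec = head[88:168].decode("ascii", errors="replace").strip()
    device = rec[4:].strip() if rec.startswith("dev=") else "unknown"
    return patient or path.stem, device


def read_edf(path: str | Path, channels: list[str] | None = None) -> Recording:
    """Read an EDF file into a Recording (microvolts, original rate).

    ``channels`` optionally restricts (and orders) the channels returned;
    a requested channel that is absent raises ChannelLookupError listing
    the labels available.  No re-referencing is applied.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    subject_id, device_id = _read_edf_ids(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # malformed header, truncated payload, ...
        raise FormatError(f"{path}: not a readable EDF file ({exc})") from exc

    # EDF labels often carry a type prefix ("EEG Fp1"); strip it.
    labels = [c.split()[-1].split("-")[0] for c in raw.ch_names]
    data = raw.get_data() * 1e6  # volts -> microvolts
    if channels is not None:
        missing = [c for c in channels if c not in labels]
        if missing:
            raise ChannelLookupError(
                f"channels {missing} not in {path.name}; available: {labels}"
            )
        idx = [labels.index(c) for c in channels]
        data, labels = data[idx], list(channels)
    return Recording(subject_id=subject_id, channels=labels,
                     fs=float(raw.info["sfreq"]), data=data, device_id=device_id)


# --------------------------------------------------------------------------
# Hypnogram / artifact mask
# --------------------------------------------------------------------------

def read_hypnogram(path: str | Path, mapping: dict[str, str] | None = None) -> Hypnogram:
    """Read a plain-text hypnogram, one stage token per 20 s epoch line.

    ``mapping`` translates a foreign dialect's tokens onto the canonical
    codes (W, N1, N2, SWS, REM, MT) before validation.
    """
    stages = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            if mapping is not None:
                tok = mapping.get(tok, tok)
            if tok not in STAGES:
                raise FormatError(
                    f"{path}: unknown stage token {tok!r} at line {lineno}"
                )
            stages.append(tok)
    if not stages:
        logger.warning("hypnogram %s is empty", path)
    return Hypnogram(stages)


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("\n".join(hyp.stages) + ("\n" if hyp.stages else ""))


def read_artifact_mask(path: str | Path) -> ArtifactMask:
    """Read a plain-text artifact mask, one 0/1 flag per 4 s segment line."""
    flags = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            if tok not in ("0", "1"):
                raise FormatError(f"{path}: expected 0 or 1 at line {lineno}, got {tok!r}")
            flags.append(tok == "1")
    return ArtifactMask(np.array(flags, dtype=bool))


def write_artifact_mask(mask: ArtifactMask, path: str | Path) -> None:
    Path(path).write_text("\n".join("1" if f else "0" for f in mask.flags) + "\n")


# --------------------------------------------------------------------------
# Subject table
# --------------------------------------------------------------------------

SUBJECT_COLUMNS = ["subject_id", "sex", "age", "raven_raw", "cft_raw", "device_id"]


def read_subject_table(path: str | Path,
                       plausible_age: tuple[float, float] = (5.0, 110.0)) -> pd.DataFrame:
    """Read and validate the subject CSV.

    Columns: subject_id, sex (F/M), age (years), raven_raw, cft_raw,
    device_id.  Missing test scores stay missing (NaN), never zero.  Every
    subject needs at least one of the two scores, a unique id, a valid sex
    code and a plausible age.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "sex": str, "device_id": str})
    missing_cols = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    df = df[SUBJECT_COLUMNS].copy()
    df["age"] = pd.to_numeric(df["age"])
    df["raven_raw"] = pd.to_numeric(df["raven_raw"])
    df["cft_raw"] = pd.to_numeric(df["cft_raw"])
    return validate_subject_table(df, plausible_age=plausible_age)


def validate_subject_table(df: pd.DataFrame,
                           plausible_age: tuple[float, float] = (5.0, 110.0)) -> pd.DataFrame:
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate subject ids: {sorted(set(dup))}")
    bad_sex = df.loc[~df["sex"].isin(["F", "M"]), "subject_id"]
    if len(bad_sex):
        raise ValidationError(f"invalid sex code for subjects: {list(bad_sex)}")
    lo, hi = plausible_age
    bad_age = df.loc[(df["age"] < lo) | (df["age"] > hi) | df["age"].isna(), "subject_id"]
    if len(bad_age):
        raise ValidationError(f"implausible age for subjects: {list(bad_age)}")
    no_score = df.loc[df["raven_raw"].isna() & df["cft_raw"].isna(), "subject_id"]
    if len(no_score):
        raise ValidationError(
            f"subjects with neither test score: {list(no_score)}"
        )
    return df.reset_index(drop=True)


def write_subject_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Spectra table (long-format CSV)
# --------------------------------------------------------------------------

def write_spectra(table: SpectraTable, path: str | Path) -> None:
    """Write a SpectraTable as long-format CSV.

    Missing subject x electrode rows are simply absent from the file; the
    reader reconstructs the missing markers from absence.
    """
    n_s, n_e, n_b = table.values.shape
    miss = table.missing
    frames = []
    for si, sid in enumerate(table.subjects):
        for ei, el in enumerate(table.electrodes):
            if miss[si, ei]:
                continue
            frames.append(pd.DataFrame({
                "subject": sid, "state": table.state, "electrode": el,
                "bin_hz": table.bins, "value": table.values[si, ei],
            }))
    if not frames:
        raise ValidationError("spectra table has no non-missing data to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_spectra(path: str | Path) -> SpectraTable:
    """Read a long-format spectra CSV back into a SpectraTable."""
    df = pd.read_csv(path, dtype={"subject": str, "state": str, "electrode": str})
    needed = {"subject", "state", "electrode", "bin_hz", "value"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(needed)}")
    states = df["state"].unique()
    if len(states) != 1:
        raise FormatError(f"{path}: expected a single state, found {list(states)}")
    state = states[0]
    bins = np.sort(df["bin_hz"].unique())
    if len(bins) != N_BINS or not np.allclose(bins, FREQ_BINS):
        raise FormatError(
            f"{path}: frequency grid has {len(bins)} bins, expected the "
            f"{N_BINS}-bin 1-40 Hz grid"
        )
    subjects = list(dict.fromkeys(df["subject"]))
    file_elecs = set(df["electrode"])
    electrodes = [e for e in MONTAGE18 if e in file_elecs]
    electrodes += sorted(file_elecs - set(electrodes))
    values = np.full((len(subjects), len(electrodes), N_BINS), np.nan)
    s_idx = {s: i for i, s in enumerate(subjects)}
    e_idx = {e: i for i, e in enumerate(electrodes)}
    b_idx = {round(b, 4): i for i, b in enumerate(FREQ_BINS)}
    si = df["subject"].map(s_idx).to_numpy()
    ei = df["electrode"].map(e_idx).to_numpy()
    bi = df["bin_hz"].round(4).map(b_idx).to_numpy()
    values[si, ei, bi] = df["value"].to_numpy()
    # partial electrode rows (some bins written, some not) are malformed
    partial = np.isnan(values).any(axis=2) & ~np.isnan(values).all(axis=2)
    if partial.any():
        raise FormatError(f"{path}: electrodes with incomplete bin coverage")
    return SpectraTable(state=state, subjects=subjects, electrodes=electrodes,
                        values=values)
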
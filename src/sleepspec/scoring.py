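"""Composite intelligence scoring on the Raven APM raw-score scale.

Subjects completed one or both of two nonverbal tests: Raven Advanced
Progressive Matrices (APM) and the Culture Fair Test (CFT).  Scores are
unified as a Raven Equivalent Score (RES):

* an APM raw score is its own RES;
* a CFT raw score is first converted to IQ by age-dependent norms, the IQ
  to a percentile under a normal IQ distribution (mean 100, configurable
  SD), and the percentile to the APM raw score holding that percentile in
  the APM standardization table;
* when both tests are available the two RES values are averaged.

Published norm tables are copyrighted and are therefore a pluggable CSV
resource.  ``synthetic_norms()`` builds clearly non-normative monotone
tables so the machinery is fully testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import FormatError, ValidationError


@dataclass
class NormTables:
    """Pluggable norm tables backing the CFT -> RES conversion.

    cft_to_iq: columns age_lo, age_hi, cft_raw, iq (age bands; a band of
    zero width at one age gives continuous-age behaviour via adjacent
    bands).  Within a band, IQ is linearly interpolated over cft_raw.

    apm_table: columns percentile, raven_raw; monotonically non-decreasing
    raw score over percentile.  Lookup interpolates linearly and breaks
    ties toward the lower raw score.
    """

    cft_to_iq: pd.DataFrame
    apm_table: pd.DataFrame
    iq_sd: float = 15.0

    def __post_init__(self) -> None:
        need = {"age_lo", "age_hi", "cft_raw", "iq"}
        if not need.issubset(self.cft_to_iq.columns):
            raise FormatError(f"cft_to_iq needs columns {sorted(need)}")
        if not {"percentile", "raven_raw"}.issubset(self.apm_table.columns):
            raise FormatError("apm_table needs columns percentile, raven_raw")
        t = self.apm_table.sort_values("percentile")
        if (t["percentile"].le(0) | t["percentile"].ge(100)).any():
            raise ValidationError("APM percentiles must lie strictly in (0, 100)")
        if np.any(np.diff(t["raven_raw"].to_numpy()) < 0):
            raise ValidationError("APM raw score must be non-decreasing in percentile")
        self.apm_table = t.reset_index(drop=True)

    @property
    def apm_range(self) -> tuple[float, float]:
        r = self.apm_table["raven_raw"]
        return float(r.min()), float(r.max())

    def iq_from_cft(self, cft_raw: float, age: float) -> float:
        band = self.cft_to_iq[(self.cft_to_iq["age_lo"] <= age)
                              & (age <= self.cft_to_iq["age_hi"])]
        if band.empty:
            lo, hi = self.cft_to_iq["age_lo"].min(), self.cft_to_iq["age_hi"].max()
            raise ValidationError(
                f"age {age} outside norm coverage ({lo}-{hi} years)"
            )
        band = band.sort_values("cft_raw")
        raws, iqs = band["cft_raw"].to_numpy(float), band["iq"].to_numpy(float)
        if not raws.min() <= cft_raw <= raws.max():
            raise ValidationError(
                f"CFT raw score {cft_raw} outside norm range "
                f"[{raws.min()}, {raws.max()}] for age {age}"
            )
        return float(np.interp(cft_raw, raws, iqs))

    def percentile_from_iq(self, iq: float) -> float:
        return float(100.0 * norm.cdf(iq, loc=100.0, scale=self.iq_sd))

    def apm_from_percentile(self, percentile: float) -> float:
        pct = self.apm_table["percentile"].to_numpy(float)
        raw = self.apm_table["raven_raw"].to_numpy(float)
        # clamp outside the tabulated range; interpolate linearly inside,
        # which resolves percentile ties toward the lower raw score because
        # np.interp takes the first matching knot.
        return float(np.interp(percentile, pct, raw))


@dataclass
class ResScore:
    subject_id: str
    res: float
    provenance: str  # APM_only | CFT_only | averaged


def res_from_apm(raven_raw: float, norms: NormTables,
                 subject_id: str = "") -> ResScore:
    """RES of an APM test is the raw score itself."""
    lo, hi = norms.apm_range
    if not lo <= raven_raw <= hi:
        raise ValidationError(
            f"raven_raw {raven_raw} outside APM table range [{lo}, {hi}]"
        )
    return ResScore(subject_id, float(raven_raw), "APM_only")


def res_from_cft(cft_raw: float, age: float, norms: NormTables,
                 subject_id: str = "") -> ResScore:
    """RES of a CFT score: CFT -> IQ -> percentile -> APM raw score."""
    iq = norms.iq_from_cft(cft_raw, age)
    pct = norms.percentile_from_iq(iq)
    return ResScore(subject_id, norms.apm_from_percentile(pct), "CFT_only")


def res_composite(raven_raw: float | None, cft_raw: float | None, age: float,
                  norms: NormTables, subject_id: str = "") -> ResScore:
    """Composite RES: mean of the two per-test RES values when both exist."""
    has_apm = raven_raw is not None and not np.isnan(raven_raw)
    has_cft = cft_raw is not None and not np.isnan(cft_raw)
    if not has_apm and not has_cft:
        raise ValidationError(f"subject {subject_id!r}: no test score available")
    if has_apm and not has_cft:
        return res_from_apm(raven_raw, norms, subject_id)
    if has_cft and not has_apm:
        return res_from_cft(cft_raw, age, norms, subject_id)
    a = res_from_apm(raven_raw, norms, subject_id).res
    c = res_from_cft(cft_raw, age, norms, subject_id).res
    return ResScore(subject_id, (a + c) / 2.0, "averaged")


def score_subjects(subjects: pd.DataFrame, norms: NormTables) -> pd.DataFrame:
    """RES for every row of a subject table -> (subject_id, res, provenance)."""
    rows = []
    for _, r in subjects.iterrows():
        s = res_composite(r["raven_raw"], r["cft_raw"], r["age"], norms,
                          subject_id=r["subject_id"])
        rows.append({"subject_id": s.subject_id, "res": s.res,
                     "provenance": s.provenance})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Synthetic norms and CSV plumbing
# --------------------------------------------------------------------------

def synthetic_norms(iq_sd: float = 15.0) -> NormTables:
    """Synthetic, non-normative monotone norm tables for testing.

    CFT->IQ: within three broad age bands, IQ rises linearly with the raw
    score; older bands need slightly higher raw scores for the same IQ.
    APM table: raw scores 4..36 spread over percentiles 1..99.  These
    numbers are invented and carry no psychometric meaning.
    """
    bands = [(10.0, 29.99, 40.0), (30.0, 49.99, 42.0), (50.0, 110.0, 44.0)]
    rows = []
    for lo, hi, mid_raw in bands:
        for raw in range(10, 61, 2):
            rows.append({"age_lo": lo, "age_hi": hi, "cft_raw": float(raw),
                         "iq": 100.0 + (raw - mid_raw) * 2.5})
    cft = pd.DataFrame(rows)
    pct = np.linspace(1.0, 99.0, 33)
    apm = pd.DataFrame({"percentile": pct,
                        "raven_raw": np.arange(4.0, 37.0)})
    return NormTables(cft_to_iq=cft, apm_table=apm, iq_sd=iq_sd)


def read_norms(directory: str | Path, iq_sd: float = 15.0) -> NormTables:
    d = Path(directory)
    return NormTables(cft_to_iq=pd.read_csv(d / "cft_to_iq.csv"),
                      apm_table=pd.read_csv(d / "apm_table.csv"),
                      iq_sd=iq_sd)


def write_norms(norms: NormTables, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    norms.cft_to_iq.to_csv(d / "cft_to_iq.csv", index=False)
    norms.apm_table.to_csv(d / "apm_table.csv", index=False)
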
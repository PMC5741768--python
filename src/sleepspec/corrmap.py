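"""Mass-univariate age-partial correlation maps and between-sex comparisons.

For each sex and sleep state, the Pearson partial correlation (controlling
for age) between the trait score and relative log power is computed in every
electrode x frequency-bin cell, using only subjects of that sex for whom the
electrode is present.  The partial correlation is the plain Pearson
correlation of the least-squares residuals of both variables after
regressing out age; its two-tailed p-value comes from
t = r * sqrt((n-3) / (1-r^2)) on n-3 degrees of freedom (one covariate).

Sex differences in correlation strength are tested with Fisher's r-to-z
method: z = (atanh(r_f) - atanh(r_m)) / sqrt(1/(n_f-3) + 1/(n_m-3)),
referred to the standard normal, two-tailed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, ValidationError
from .io import N_BINS, SpectraTable

logger = logging.getLogger(__name__)

MIN_CELL_N = 5


@dataclass
class CorrMap:
    """Electrode x bin grid of age-partial correlations for one sex/state."""

    state: str
    sex: str
    electrodes: list[str]
    r: np.ndarray  # (n_electrodes, 157); NaN = missing cell
    p: np.ndarray
    n: np.ndarray  # subjects contributing per cell (int)
    bins: np.ndarray

    def critical_r(self, alpha: float = 0.05) -> np.ndarray:
        """Per-cell |r| threshold at the given two-tailed alpha."""
        df = np.maximum(self.n - 3, 1)
        t = stats.t.ppf(1 - alpha / 2, df)
        return t / np.sqrt(t ** 2 + df)


@dataclass
class DimorphismTest:
    electrode: str
    bin_hz: float
    r_female: float
    r_male: float
    n_female: int
    n_male: int
    z: float
    p: float


def residualize(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Least-squares residuals of ``values`` on [1, covariate].

    ``values`` may be a vector or an (n, k) matrix of columns sharing the
    covariate.  A constant covariate degrades gracefully to mean-centering.
    The residuals are orthogonal to the covariate, and the Pearson
    correlation of two residual series equals the partial correlation of
    the originals given the covariate.
    """
    values = np.asarray(values, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    n = covariate.shape[0]
    if values.shape[0] != n:
        raise ValidationError("values and covariate lengths differ")
    if n < 3:
        raise ValidationError("need at least 3 observations to residualize")
    if np.ptp(covariate) == 0:
        return values - values.mean(axis=0)
    design = np.column_stack([np.ones(n), covariate])
    q, _ = np.linalg.qr(design)
    return values - q @ (q.T @ values)


def partial_corr(x: np.ndarray, y: np.ndarray,
                 covariate: np.ndarray) -> tuple[float, float, int]:
    """Age-partial Pearson correlation of two vectors -> (r, p, n).

    Incomplete triples (any NaN) are dropped.  Zero residual variance in
    either variable leaves the correlation undefined: (nan, nan, n).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.asarray(covariate, float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(c)
    x, y, c = x[ok], y[ok], c[ok]
    n = len(x)
    if n < MIN_CELL_N:
        raise ValidationError(f"need >= {MIN_CELL_N} complete triples, got {n}")
    r, p = _partial_corr_columns(x[:, None], y, c)
    return float(r[0]), float(p[0]), n


def _partial_corr_columns(X: np.ndarray, y: np.ndarray,
                          covariate: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized partial correlation of each column of X with y given the
    covariate.  Returns (r, p) arrays of length X.shape[1]; undefined cells
    (zero residual variance) are NaN."""
    n = len(y)
    rx = residualize(X, covariate)
    ry = residualize(y, covariate)
    sx = np.sqrt((rx ** 2).sum(axis=0))
    sy = float(np.sqrt((ry ** 2).sum()))
    # residual variance indistinguishable from rounding error (e.g. a
    # variable identical to the covariate) leaves r undefined
    sx0 = np.sqrt(((X - X.mean(axis=0)) ** 2).sum(axis=0))
    sy0 = float(np.sqrt(((y - y.mean()) ** 2).sum()))
    defined = (sx > 1e-8 * np.maximum(sx0, 1e-300)) & (sy > 1e-8 * max(sy0, 1e-300))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rx * ry[:, None]).sum(axis=0) / (sx * sy)
    r = np.where(defined, r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    df = n - 3
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isfinite(r), np.where(np.abs(r) >= 1.0, 0.0, p), np.nan)
    return r, p


def build_corrmap(spectra: SpectraTable, res: pd.DataFrame,
                  subjects: pd.DataFrame, sex: str,
                  min_n: int = MIN_CELL_N) -> CorrMap:
    """Age-partial correlation map for one sex over the full grid.

    ``res`` must have columns subject_id/res and ``subjects`` columns
    subject_id/sex/age.  Every subject in the spectra table must appear in
    both tables (anything else indicates an alignment bug upstream).
    Cells with fewer than ``min_n`` contributing subjects are marked
    missing with a warning.
    """
    if sex not in ("F", "M"):
        raise ValidationError("sex must be 'F' or 'M'")
    res_map = dict(zip(res["subject_id"], res["res"]))
    sub = subjects.set_index("subject_id")
    missing_ids = [s for s in spectra.subjects
                   if s not in res_map or s not in sub.index]
    if missing_ids:
        raise AlignmentError(
            f"spectra subjects missing from res/subject tables: {missing_ids[:5]}"
        )
    sel = [i for i, s in enumerate(spectra.subjects) if sub.loc[s, "sex"] == sex]
    vals = spectra.values[sel]
    y = np.array([res_map[spectra.subjects[i]] for i in sel], float)
    age = np.array([sub.loc[spectra.subjects[i], "age"] for i in sel], float)

    n_e = len(spectra.electrodes)
    r = np.full((n_e, N_BINS), np.nan)
    p = np.full((n_e, N_BINS), np.nan)
    n = np.zeros((n_e, N_BINS), dtype=int)
    for ei in range(n_e):
        ok = ~np.isnan(vals[:, ei, :]).any(axis=1) & np.isfinite(y) & np.isfinite(age)
        n_ok = int(ok.sum())
        n[ei, :] = n_ok
        if n_ok < min_n:
            logger.warning("electrode %s: only %d %s subjects, cells marked missing",
                           spectra.electrodes[ei], n_ok, sex)
            continue
        r[ei], p[ei] = _partial_corr_columns(vals[ok, ei, :], y[ok], age[ok])
    return CorrMap(state=spectra.state, sex=sex, electrodes=list(spectra.electrodes),
                   r=r, p=p, n=n, bins=spectra.bins.copy())


# --------------------------------------------------------------------------
# Fisher r-to-z sex comparison
# --------------------------------------------------------------------------

def normal_two_tailed_p(z: float) -> float:
    """p = 2 * (1 - Phi(|z|)) for a standard-normal statistic."""
    if not np.isfinite(z):
        raise ValidationError("z must be finite")
    return float(2.0 * stats.norm.sf(abs(z)))


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z test for the difference of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-tailed p.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValidationError("|r| must be < 1 for the Fisher transform")
    if n1 <= 6 or n2 <= 6:
        raise ValidationError("need n > 6 in both groups")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = float((np.arctanh(r1) - np.arctanh(r2)) / se)
    return z, normal_two_tailed_p(z)


def dimorphism_test(map_f: CorrMap, map_m: CorrMap, electrode: str,
                    bin_hz: float) -> DimorphismTest:
    """Compare female vs male correlation at one grid cell."""
    ei = map_f.electrodes.index(electrode)
    bi = int(np.argmin(np.abs(map_f.bins - bin_hz)))
    em = map_m.electrodes.index(electrode)
    r_f, n_f = float(map_f.r[ei, bi]), int(map_f.n[ei, bi])
    r_m, n_m = float(map_m.r[em, bi]), int(map_m.n[em, bi])
    if np.isnan(r_f) or np.isnan(r_m):
        raise ValidationError(f"cell {electrode}@{bin_hz} Hz missing in one sex")
    z, p = fisher_compare(r_f, n_f, r_m, n_m)
    return DimorphismTest(electrode=electrode, bin_hz=float(map_f.bins[bi]),
                          r_female=r_f, r_male=r_m, n_female=n_f, n_male=n_m,
                          z=z, p=p)


def corrmap_to_frame(cm: CorrMap) -> pd.DataFrame:
    """Long-format export of a correlation map."""
    rows = []
    for ei, el in enumerate(cm.electrodes):
        rows.append(pd.DataFrame({
            "state": cm.state, "sex": cm.sex, "electrode": el,
            "bin_hz": cm.bins, "r": cm.r[ei], "p": cm.p[ei], "n": cm.n[ei],
        }))
    return pd.concat(rows, ignore_index=True)
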
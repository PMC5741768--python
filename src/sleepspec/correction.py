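"""Multiple-comparisons control over the electrode x frequency grid.

Two complementary procedures are provided.

**Ruger areas.**  Neighbouring bins and electrodes are strongly correlated,
so Bonferroni over 18 x 157 cells is hopelessly conservative.  Instead,
contiguous frequency runs in which at least one electrode is nominally
significant (p < alpha) form *areas of potential significance*.  Areas whose
significant cells all sit on a single electrode, or which span fewer than 4
bins (< 1 Hz), are discarded as likely narrow-band artifacts or outliers.
An area is declared significant when at least 50% of its significant cells
also pass p < alpha/2, or at least a third pass p < alpha/3 (the exact
fraction 0.05/3 = 0.0166.. is used, not its 0.016 rounding).

**Permutation max-statistic (rmax).**  After residualizing both trait and
spectra on age, subject labels of the trait residuals are permuted; each
permutation records the maximum |r| over a test family, and the corrected
p-value of a cell is the (1-offset) fraction of permutation maxima at or
above its observed |r|.  The default family is the set of electrodes within
each frequency bin; a grid-wide family is available and is never less
strict.  The method assumes complete data, so missing channels are first
imputed on a reduced 12-channel montage: a missing Fz is the mean of F3/F4,
a missing Cz the mean of C3/C4, and any other missing channel the mean of
its available configured neighbours (on relative log-power values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .corrmap import CorrMap, residualize
from .exceptions import ProcessingError, ValidationError
from .io import SpectraTable
from .montage import DEFAULT_ADJACENCY, MONTAGE12

logger = logging.getLogger(__name__)

RUGER_HALF_FRACTION = 0.5
RUGER_THIRD_FRACTION = 1.0 / 3.0


@dataclass
class RugerArea:
    """A contiguous frequency run of nominally significant cells."""

    bin_range: tuple[float, float]
    member_cells: list[tuple[str, float]]  # (electrode, bin_hz) significant cells
    n_sig: int
    frac_half: float   # fraction of member cells with p < alpha/2
    frac_third: float  # fraction with p < alpha/3
    electrodes_involved: list[str]
    decision: bool
    max_cell: tuple[str, float, float]  # (electrode, bin_hz, r) at max |r|


@dataclass
class PermResult:
    """Family-wise corrected p-values from the rmax permutation scheme."""

    electrodes: list[str]
    bins: np.ndarray
    p_corr: np.ndarray  # (n_electrodes, n_bins)
    r_obs: np.ndarray
    n_perm: int
    family: str  # 'bin' or 'grid'
    seed: int | None


@dataclass
class SignificantRange:
    first_hz: float
    last_hz: float
    channels: list[str]


def ruger_decision(frac_half: float, frac_third: float) -> bool:
    """The area-level decision rule on the two member-cell fractions."""
    return frac_half >= RUGER_HALF_FRACTION or frac_third >= RUGER_THIRD_FRACTION


def find_ruger_areas(corrmap: CorrMap, alpha: float = 0.05,
                     min_bins: int = 4, min_electrodes: int = 2) -> list[RugerArea]:
    """Detect and evaluate Ruger areas on a correlation map.

    Areas are maximal contiguous runs of frequency bins that each contain
    at least one cell with p < alpha.  Runs spanning fewer than
    ``min_bins`` bins or whose significant cells involve fewer than
    ``min_electrodes`` electrodes are dropped.  The returned areas carry
    the decision and the cell of maximal |r| (ties: lower frequency first,
    then montage order).
    """
    p = corrmap.p
    with np.errstate(invalid="ignore"):
        sig = np.where(np.isnan(p), False, p < alpha)
    bin_any = sig.any(axis=0)
    areas: list[RugerArea] = []
    b = 0
    n_bins = len(corrmap.bins)
    while b < n_bins:
        if not bin_any[b]:
            b += 1
            continue
        b_end = b
        while b_end + 1 < n_bins and bin_any[b_end + 1]:
            b_end += 1
        run = range(b, b_end + 1)
        cells = [(ei, bi) for bi in run for ei in range(len(corrmap.electrodes))
                 if sig[ei, bi]]
        elecs = sorted({ei for ei, _ in cells})
        span = b_end - b + 1
        if span >= min_bins and len(elecs) >= min_electrodes:
            pvals = np.array([p[ei, bi] for ei, bi in cells])
            frac_half = float(np.mean(pvals < alpha / 2.0))
            frac_third = float(np.mean(pvals < alpha / 3.0))
            # max |r| with ties broken toward lower frequency, then montage order
            best = min(cells, key=lambda c: (-abs(corrmap.r[c[0], c[1]]), c[1], c[0]))
            areas.append(RugerArea(
                bin_range=(float(corrmap.bins[b]), float(corrmap.bins[b_end])),
                member_cells=[(corrmap.electrodes[ei], float(corrmap.bins[bi]))
                              for ei, bi in cells],
                n_sig=len(cells),
                frac_half=frac_half,
                frac_third=frac_third,
                electrodes_involved=[corrmap.electrodes[ei] for ei in elecs],
                decision=ruger_decision(frac_half, frac_third),
                max_cell=(corrmap.electrodes[best[0]], float(corrmap.bins[best[1]]),
                          float(corrmap.r[best[0], best[1]])),
            ))
        b = b_end + 1
    return areas


def decide_ruger(area: RugerArea) -> bool:
    """Re-evaluate the decision rule on an area's stored fractions."""
    if area.n_sig < 1:
        raise ValidationError("area has no member cells")
    return ruger_decision(area.frac_half, area.frac_third)


# --------------------------------------------------------------------------
# Channel imputation
# --------------------------------------------------------------------------

def impute_channels(spectra: SpectraTable,
                    target_montage: list[str] | None = None,
                    adjacency: dict[str, list[str]] | None = None) -> SpectraTable:
    """Reduce to the 12-channel montage, imputing missing channels.

    Imputation averages relative log-power values of available neighbours
    (Fz from F3/F4, Cz from C3/C4 via the adjacency table).  Neighbours may
    be drawn from the full input montage, not only the target.  A missing
    channel with no available neighbour raises, naming the subject.
    """
    target = list(target_montage) if target_montage is not None else list(MONTAGE12)
    adj = adjacency if adjacency is not None else DEFAULT_ADJACENCY
    missing_from_input = [c for c in target if c not in spectra.electrodes
                          and c not in adj]
    if missing_from_input:
        raise ValidationError(f"no adjacency entry for channels {missing_from_input}")
    n_s = len(spectra.subjects)
    out = np.full((n_s, len(target), len(spectra.bins)), np.nan)
    e_idx = {e: i for i, e in enumerate(spectra.electrodes)}
    for si in range(n_s):
        for ti, ch in enumerate(target):
            if ch in e_idx and not np.isnan(spectra.values[si, e_idx[ch]]).any():
                out[si, ti] = spectra.values[si, e_idx[ch]]
                continue
            neighbours = [nb for nb in adj.get(ch, [])
                          if nb in e_idx and not np.isnan(spectra.values[si, e_idx[nb]]).any()]
            if not neighbours:
                raise ProcessingError(
                    f"subject {spectra.subjects[si]!r}: channel {ch} missing with "
                    f"no available neighbours"
                )
            out[si, ti] = np.mean(
                [spectra.values[si, e_idx[nb]] for nb in neighbours], axis=0
            )
    return SpectraTable(state=spectra.state, subjects=list(spectra.subjects),
                        electrodes=target, values=out, bins=spectra.bins.copy())


# --------------------------------------------------------------------------
# Permutation correction
# --------------------------------------------------------------------------

def permutation_correct(spectra: SpectraTable, res: np.ndarray, age: np.ndarray,
                        n_perm: int = 5000, family: str = "bin",
                        seed: int | None = None, strict: bool = True) -> PermResult:
    """Family-wise corrected p-values by the rmax permutation scheme.

    ``res`` and ``age`` are aligned to ``spectra.subjects``.  Both trait
    and every cell are residualized on age; each permutation shuffles the
    subject labels of the trait residuals and records the maximum |r| over
    the family ('bin': electrodes within each frequency bin, the default;
    'grid': every cell).  Corrected p = (1 + #{max >= |r_obs|}) / (n_perm+1),
    which can never reach zero.  Identical seeds reproduce identical
    p-values.
    """
    if family not in ("bin", "grid"):
        raise ValidationError("family must be 'bin' or 'grid'")
    if n_perm < 100:
        logger.warning("n_perm=%d is very low; corrected p-values are coarse", n_perm)
    if seed is None and strict:
        raise ValidationError("a seed is required for reproducible permutation runs")
    vals = spectra.values
    if np.isnan(vals).any():
        raise ValidationError(
            "permutation correction requires complete data; impute channels first"
        )
    res = np.asarray(res, float)
    age = np.asarray(age, float)
    n, n_e, n_b = vals.shape
    if len(res) != n or len(age) != n:
        raise ValidationError("res/age not aligned with spectra subjects")

    X = residualize(vals.reshape(n, n_e * n_b), age)
    y = residualize(res, age)
    Xn = X / np.linalg.norm(X, axis=0, keepdims=True)
    yn = y / np.linalg.norm(y)
    r_obs = (Xn.T @ yn).reshape(n_e, n_b)

    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for j in range(n_perm):
        perms[:, j] = yn[rng.permutation(n)]
    R = np.abs(Xn.T @ perms).reshape(n_e, n_b, n_perm)

    if family == "grid":
        fam_max = R.max(axis=(0, 1))  # (n_perm,)
        exceed = fam_max[None, None, :] >= np.abs(r_obs)[:, :, None]
    else:
        fam_max = R.max(axis=0)  # (n_bins, n_perm)
        exceed = fam_max[None, :, :] >= np.abs(r_obs)[:, :, None]
    p_corr = (1.0 + exceed.sum(axis=2)) / (n_perm + 1.0)
    return PermResult(electrodes=list(spectra.electrodes), bins=spectra.bins.copy(),
                      p_corr=p_corr, r_obs=r_obs, n_perm=n_perm, family=family,
                      seed=seed)


def summarize_significant_ranges(result: PermResult,
                                 alpha: float = 0.05) -> list[SignificantRange]:
    """Contiguous frequency ranges with at least one corrected-significant
    cell, listing every channel significant somewhere in the range; ranges
    whose significant cells all sit on a single channel are dropped."""
    sig = result.p_corr < alpha
    bin_any = sig.any(axis=0)
    ranges: list[SignificantRange] = []
    b, n_bins = 0, len(result.bins)
    while b < n_bins:
        if not bin_any[b]:
            b += 1
            continue
        b_end = b
        while b_end + 1 < n_bins and bin_any[b_end + 1]:
            b_end += 1
        chans = [result.electrodes[ei] for ei in range(len(result.electrodes))
                 if sig[ei, b:b_end + 1].any()]
        if len(chans) >= 2:
            ranges.append(SignificantRange(first_hz=float(result.bins[b]),
                                           last_hz=float(result.bins[b_end]),
                                           channels=chans))
        b = b_end + 1
    return ranges
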
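"""End-to-end orchestration: spectra -> correlate -> correct -> compare.

``analyze_cohort`` is the in-memory core: given spectra tables per state, a
subject table and an RES table, it builds per-sex age-partial correlation
maps, detects and decides Ruger areas, runs the permutation correction on
the imputed 12-channel montage, and performs the Fisher r-to-z sex
comparison at each area's maximal-association cell.  ``run_pipeline`` wraps
it with file I/O, logging and a JSON report for the command line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .corrmap import (CorrMap, DimorphismTest, build_corrmap, corrmap_to_frame,
                      dimorphism_test, partial_corr)
from .correction import (PermResult, RugerArea, SignificantRange,
                         find_ruger_areas, impute_channels, permutation_correct,
                         summarize_significant_ranges)
from .exceptions import ValidationError
from .io import (SpectraTable, read_spectra, read_subject_table)
from .scoring import score_subjects

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and options for a full pipeline run."""

    spectra_paths: dict[str, str]       # state -> long-format spectra CSV
    subjects_path: str
    res_path: str | None = None         # precomputed RES CSV; else norms_dir
    norms_dir: str | None = None
    states: tuple[str, ...] = ("NREM", "REM")
    sexes: tuple[str, ...] = ("F", "M")
    alpha: float = 0.05
    n_perm: int = 5000
    family: str = "bin"
    seed: int | None = None
    out_dir: str = "results"
    make_plots: bool = False

    def validate(self) -> None:
        for state, p in self.spectra_paths.items():
            if not Path(p).exists():
                raise ValidationError(f"spectra file for {state} not found: {p}")
        if not Path(self.subjects_path).exists():
            raise ValidationError(f"subject table not found: {self.subjects_path}")
        if self.res_path is None and self.norms_dir is None:
            raise ValidationError("need either res_path or norms_dir to obtain RES")
        if self.n_perm > 0 and self.seed is None:
            raise ValidationError("a seed is mandatory when permutation is enabled")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        cfg = json.loads(Path(path).read_text())
        cfg["states"] = tuple(cfg.get("states", ("NREM", "REM")))
        cfg["sexes"] = tuple(cfg.get("sexes", ("F", "M")))
        return cls(**cfg)


@dataclass
class RunReport:
    """Everything the analysis concluded, in reportable form."""

    corrmaps: dict[tuple[str, str], CorrMap]
    ruger: dict[tuple[str, str], list[RugerArea]]
    perm: dict[tuple[str, str], PermResult]
    perm_ranges: dict[tuple[str, str], list[SignificantRange]]
    dimorphism: list[DimorphismTest]
    config_echo: dict = field(default_factory=dict)
    version: str = ""

    def significant_areas(self, state: str, sex: str) -> list[RugerArea]:
        return [a for a in self.ruger.get((state, sex), []) if a.decision]

    def corroborated_areas(self, state: str, sex: str) -> list[RugerArea]:
        """Ruger-significant areas that overlap a permutation-significant
        frequency range — the conjunction of the two correction methods.

        The Ruger fraction rule alone rejects a null area roughly half the
        time (among truly null nominally significant cells, about half pass
        the alpha/2 threshold by construction), so headline findings are
        only those corroborated by the family-wise permutation control.
        """
        ranges = self.perm_ranges.get((state, sex), [])
        out = []
        for a in self.significant_areas(state, sex):
            lo, hi = a.bin_range
            if any(r.first_hz <= hi and lo <= r.last_hz for r in ranges):
                out.append(a)
        return out

    def to_dict(self) -> dict:
        def area(a: RugerArea) -> dict:
            return {"bin_range": list(a.bin_range), "n_sig": a.n_sig,
                    "frac_half": a.frac_half, "frac_third": a.frac_third,
                    "electrodes": a.electrodes_involved, "decision": a.decision,
                    "max_cell": list(a.max_cell)}

        return {
            "version": self.version,
            "config": self.config_echo,
            "ruger_areas": {f"{st}/{sx}": [area(a) for a in areas]
                            for (st, sx), areas in self.ruger.items()},
            "permutation_ranges": {
                f"{st}/{sx}": [dataclasses.asdict(r) for r in ranges]
                for (st, sx), ranges in self.perm_ranges.items()},
            "dimorphism": [dataclasses.asdict(d) for d in self.dimorphism],
        }


def analyze_cohort(spectra_by_state: dict[str, SpectraTable],
                   subjects: pd.DataFrame, res: pd.DataFrame,
                   alpha: float = 0.05, n_perm: int = 5000,
                   family: str = "bin", seed: int | None = None,
                   sexes: tuple[str, ...] = ("F", "M"),
                   do_permutation: bool = True) -> RunReport:
    """Run the statistical analysis on in-memory tables.

    The Fisher sex comparison is evaluated at the maximal-association cell
    of every Ruger area of potential significance found in either sex
    (including areas that fail the decision rule, whose effect sizes are
    still of interest).
    """
    corrmaps: dict[tuple[str, str], CorrMap] = {}
    ruger: dict[tuple[str, str], list[RugerArea]] = {}
    perm: dict[tuple[str, str], PermResult] = {}
    perm_ranges: dict[tuple[str, str], list[SignificantRange]] = {}
    dimorphism: list[DimorphismTest] = []

    res_map = dict(zip(res["subject_id"], res["res"]))
    sub_idx = subjects.set_index("subject_id")

    for state, spectra in spectra_by_state.items():
        for sex in sexes:
            cm = build_corrmap(spectra, res, subjects, sex)
            corrmaps[(state, sex)] = cm
            ruger[(state, sex)] = find_ruger_areas(cm, alpha=alpha)

        if do_permutation and n_perm > 0:
            imputed = impute_channels(spectra)
            for i, sex in enumerate(sexes):
                ids = [s for s in imputed.subjects if sub_idx.loc[s, "sex"] == sex]
                sub_tab = imputed.subset_subjects(ids)
                y = np.array([res_map[s] for s in ids], float)
                a = np.array([sub_idx.loc[s, "age"] for s in ids], float)
                # distinct sub-streams per state/sex so runs are independent
                sub_seed = None if seed is None else (seed + 1000 * i
                                                     + 7919 * (state == "REM"))
                pr = permutation_correct(sub_tab, y, a, n_perm=n_perm,
                                         family=family, seed=sub_seed)
                perm[(state, sex)] = pr
                perm_ranges[(state, sex)] = summarize_significant_ranges(pr, alpha)

        # sex comparison at each area's maximal cell, F vs M
        if set(("F", "M")).issubset(sexes):
            tested: set[tuple[str, float]] = set()
            for sex in sexes:
                for a in ruger[(state, sex)]:
                    el, hz, _ = a.max_cell
                    if (el, hz) in tested:
                        continue
                    tested.add((el, hz))
                    try:
                        dimorphism.append(
                            dimorphism_test(corrmaps[(state, "F")],
                                            corrmaps[(state, "M")], el, hz))
                    except ValidationError as exc:
                        logger.warning("sex comparison skipped at %s %g Hz: %s",
                                       el, hz, exc)
    return RunReport(corrmaps=corrmaps, ruger=ruger, perm=perm,
                     perm_ranges=perm_ranges, dimorphism=dimorphism,
                     version=__version__)


def run_pipeline(config: RunConfig) -> RunReport:
    """File-based pipeline run: load, analyze, persist all artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def checksum(p: str) -> str:
        return hashlib.sha256(Path(p).read_bytes()).hexdigest()[:12]

    subjects = read_subject_table(config.subjects_path)
    logger.info("stage=load subjects=%d sha=%s", len(subjects),
                checksum(config.subjects_path))
    if config.res_path is not None:
        res = pd.read_csv(config.res_path, dtype={"subject_id": str})
    else:
        from .scoring import read_norms
        res = score_subjects(subjects, read_norms(config.norms_dir))
        res.to_csv(out / "res.csv", index=False)

    spectra_by_state = {}
    for state in config.states:
        try:
            spectra_by_state[state] = read_spectra(config.spectra_paths[state])
        except KeyError:
            raise ValidationError(f"no spectra path configured for state {state}")
        logger.info("stage=load state=%s subjects=%d sha=%s", state,
                    len(spectra_by_state[state].subjects),
                    checksum(config.spectra_paths[state]))

    report = analyze_cohort(spectra_by_state, subjects, res,
                            alpha=config.alpha, n_perm=config.n_perm,
                            family=config.family, seed=config.seed,
                            sexes=config.sexes)
    report.config_echo = dataclasses.asdict(config)

    for (state, sex), cm in report.corrmaps.items():
        corrmap_to_frame(cm).to_csv(out / f"corrmap_{state}_{sex}.csv",
                                    index=False, float_format="%.10g")
    for (state, sex), pr in report.perm.items():
        frame = pd.DataFrame({
            "electrode": np.repeat(pr.electrodes, len(pr.bins)),
            "bin_hz": np.tile(pr.bins, len(pr.electrodes)),
            "r_obs": pr.r_obs.ravel(),
            "p_corrected": pr.p_corr.ravel(),
        })
        frame.to_csv(out / f"perm_{state}_{sex}.csv", index=False,
                     float_format="%.10g")
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    if config.make_plots:
        for (state, sex), cm in report.corrmaps.items():
            plot_spectrocorrelogram(
                cm, out / f"spectrocorrelogram_{state}_{sex}.png",
                alpha=config.alpha)
    return report


def plot_spectrocorrelogram(cm: CorrMap, path: str | Path,
                            alpha: float = 0.05):
    """Per-electrode r-vs-frequency curves with the critical-r line.

    The horizontal lines mark the partial correlation magnitude at which a
    cell with that electrode's n reaches two-tailed significance at
    ``alpha``.  All-missing electrodes get an annotated empty panel.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_e = len(cm.electrodes)
    ncol = 3
    nrow = int(np.ceil(n_e / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.2 * nrow),
                             sharex=True, sharey=True, squeeze=False)
    crit = cm.critical_r(alpha)
    for ei, el in enumerate(cm.electrodes):
        ax = axes[ei // ncol][ei % ncol]
        if np.isnan(cm.r[ei]).all():
            ax.text(0.5, 0.5, f"{el}: no data", transform=ax.transAxes,
                    ha="center", va="center")
            continue
        ax.plot(cm.bins, cm.r[ei], lw=0.8, color="k")
        if np.nanmin(cm.p[ei]) < alpha:
            c = crit[ei, 0]
            ax.axhline(c, color="r", lw=0.6)
            ax.axhline(-c, color="r", lw=0.6)
        ax.axhline(0, color="0.7", lw=0.5)
        ax.set_title(el, fontsize=8)
    for k in range(n_e, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.suptitle(f"{cm.state} {cm.sex}: age-partial r vs frequency")
    fig.supxlabel("frequency (Hz)")
    fig.supylabel("partial r")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def macro_correlations(macro: pd.DataFrame, subjects: pd.DataFrame,
                       res: pd.DataFrame) -> pd.DataFrame:
    """Age-partial correlations of macrostructure parameters with RES.

    ``macro`` has subject_id plus numeric columns (stage minutes etc.);
    returns one row per (sex, parameter) with r, p and n.
    """
    merged = macro.merge(subjects[["subject_id", "sex", "age"]], on="subject_id")
    merged = merged.merge(res[["subject_id", "res"]], on="subject_id")
    params = [c for c in macro.columns if c != "subject_id"]
    rows = []
    for sex in ("F", "M"):
        g = merged[merged["sex"] == sex]
        for par in params:
            try:
                r, p, n = partial_corr(g[par].to_numpy(float),
                                       g["res"].to_numpy(float),
                                       g["age"].to_numpy(float))
            except ValidationError:
                r, p, n = np.nan, np.nan, len(g)
            rows.append({"sex": sex, "parameter": par, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)
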
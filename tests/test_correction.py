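"""Ruger areas, channel imputation and permutation max-statistic control."""

import numpy as np
import pytest

from sleepspec import (FREQ_BINS, decide_ruger, find_ruger_areas,
                       impute_channels, permutation_correct, ruger_decision,
                       summarize_significant_ranges)
from sleepspec.corrmap import CorrMap
from sleepspec.correction import PermResult, RugerArea
from sleepspec.exceptions import ProcessingError, ValidationError
from tests.conftest import random_spectra


def make_corrmap(p, r=None, bins=None, electrodes=None):
    p = np.asarray(p, float)
    n_e, n_b = p.shape
    if bins is None:
        bins = FREQ_BINS[:n_b]
    if electrodes is None:
        electrodes = [f"E{i}" for i in range(n_e)]
    if r is None:
        r = 0.5 * (1 - p)  # any monotone-in-significance stand-in
    return CorrMap(state="REM", sex="F", electrodes=list(electrodes),
                   r=np.asarray(r, float), p=p,
                   n=np.full((n_e, n_b), 30), bins=np.asarray(bins, float))


def oracle_ruger(p, alpha=0.05, min_bins=4, min_electrodes=2):
    """Independent brute-force implementation used as ground truth:
    scan bins one by one, grow runs, then filter and evaluate."""
    n_e, n_b = p.shape
    sig = [[(p[e][b] < alpha) if not np.isnan(p[e][b]) else False
            for b in range(n_b)] for e in range(n_e)]
    any_sig = [any(sig[e][b] for e in range(n_e)) for b in range(n_b)]
    areas = []
    b = 0
    while b < n_b:
        if not any_sig[b]:
            b += 1
            continue
        start = b
        while b < n_b and any_sig[b]:
            b += 1
        end = b - 1
        cells = [(e, bb) for bb in range(start, end + 1)
                 for e in range(n_e) if sig[e][bb]]
        elecs = {e for e, _ in cells}
        if (end - start + 1) < min_bins or len(elecs) < min_electrodes:
            continue
        n_half = sum(1 for e, bb in cells if p[e][bb] < alpha / 2)
        n_third = sum(1 for e, bb in cells if p[e][bb] < alpha / 3)
        areas.append({
            "range": (start, end),
            "cells": sorted(cells, key=lambda c: (c[1], c[0])),
            "frac_half": n_half / len(cells),
            "frac_third": n_third / len(cells),
            "decision": (n_half / len(cells) >= 0.5) or (n_third / len(cells) >= 1 / 3),
        })
    return areas


def assert_matches_oracle(p, bins):
    cm = make_corrmap(p, bins=bins)
    got = find_ruger_areas(cm)
    expect = oracle_ruger(p)
    assert len(got) == len(expect)
    for g, e in zip(got, expect):
        assert g.bin_range == (bins[e["range"][0]], bins[e["range"][1]])
        got_cells = sorted(
            (cm.electrodes.index(el), int(np.where(bins == bz)[0][0]))
            for el, bz in g.member_cells)
        assert sorted(got_cells, key=lambda c: (c[1], c[0])) == e["cells"]
        assert g.frac_half == pytest.approx(e["frac_half"])
        assert g.frac_third == pytest.approx(e["frac_third"])
        assert g.decision == e["decision"]


class TestRugerAreas:
    def test_five_bin_area_two_electrodes(self):
        p = np.ones((3, 20))
        p[0, 5:10] = 0.01
        p[1, 5:10] = 0.04
        assert_matches_oracle(p, FREQ_BINS[:20])
        areas = find_ruger_areas(make_corrmap(p))
        assert len(areas) == 1
        assert areas[0].n_sig == 10
        assert areas[0].bin_range == (FREQ_BINS[5], FREQ_BINS[9])

    def test_single_electrode_area_discarded(self):
        p = np.ones((3, 20))
        p[1, 2:11] = 0.01
        assert find_ruger_areas(make_corrmap(p)) == []

    def test_short_area_discarded(self):
        p = np.ones((3, 20))
        p[0, 5:8] = 0.01
        p[1, 5:8] = 0.01
        assert find_ruger_areas(make_corrmap(p)) == []

    def test_missing_cells_are_not_significant(self):
        p = np.ones((3, 20))
        p[0, 5:10] = np.nan
        p[1, 5:10] = 0.01
        assert find_ruger_areas(make_corrmap(p)) == []

    def test_matches_oracle_on_random_grids(self, rng):
        for _ in range(200):
            n_e = int(rng.integers(2, 6))
            n_b = int(rng.integers(6, 30))
            p = rng.uniform(0, 1, size=(n_e, n_b))
            p[p < 0.3] = p[p < 0.3] / 10  # enrich significant cells
            assert_matches_oracle(p, FREQ_BINS[:n_b])

    def test_max_cell_tie_breaks(self):
        p = np.full((2, 6), 1.0)
        r = np.zeros((2, 6))
        p[:, 1:5] = 0.01
        r[0, 2] = 0.5
        r[1, 3] = 0.5  # tie in |r|: lower frequency (bin 2) must win
        areas = find_ruger_areas(make_corrmap(p, r=r))
        assert areas[0].max_cell == ("E0", FREQ_BINS[2], 0.5)

    def test_decision_rule(self):
        assert ruger_decision(0.793, 0.674)
        assert ruger_decision(0.63, 0.383)
        assert not ruger_decision(0.4444, 0.3111)
        # exact 0.05/3 fraction boundary, not its 0.016 rounding
        assert ruger_decision(0.0, 1 / 3)
        assert not ruger_decision(0.499, 0.333)

    def test_decide_ruger_on_area(self):
        area = RugerArea((1.0, 2.0), [("E0", 1.0)], 1, 0.6, 0.2,
                         ["E0", "E1"], True, ("E0", 1.0, 0.4))
        assert decide_ruger(area)


class TestImputation:
    def _spectra(self, rng, missing):
        from sleepspec.montage import MONTAGE18
        return random_spectra(rng, n_subjects=4, electrodes=MONTAGE18,
                              missing=missing)

    def test_midline_from_lateral_pair(self, rng):
        table = self._spectra(rng, [(0, "Fz")])
        out = impute_channels(table)
        f3 = table.values[0, table.electrodes.index("F3")]
        f4 = table.values[0, table.electrodes.index("F4")]
        fz = out.values[0, out.electrodes.index("Fz")]
        assert np.allclose(fz, (f3 + f4) / 2)
        cz_missing = self._spectra(rng, [(1, "Cz")])
        out2 = impute_channels(cz_missing)
        c3 = cz_missing.values[1, cz_missing.electrodes.index("C3")]
        c4 = cz_missing.values[1, cz_missing.electrodes.index("C4")]
        assert np.allclose(out2.values[1, out2.electrodes.index("Cz")], (c3 + c4) / 2)

    def test_no_missing_is_restriction(self, rng):
        table = self._spectra(rng, [])
        out = impute_channels(table)
        assert out.electrodes == ["Fp1", "Fp2", "F3", "Fz", "F4", "C3", "Cz",
                                  "C4", "P3", "P4", "O1", "O2"]
        for ch in out.electrodes:
            assert np.allclose(out.values[:, out.electrodes.index(ch)],
                               table.values[:, table.electrodes.index(ch)])

    def test_neighbour_average_per_adjacency(self, rng):
        table = self._spectra(rng, [(2, "O2")])
        adjacency = {"O2": ["O1", "P4"]}
        out = impute_channels(table, adjacency={**{c: [] for c in table.electrodes},
                                                **adjacency})
        o1 = table.values[2, table.electrodes.index("O1")]
        p4 = table.values[2, table.electrodes.index("P4")]
        assert np.allclose(out.values[2, out.electrodes.index("O2")], (o1 + p4) / 2)

    def test_unavailable_neighbours_named(self, rng):
        table = self._spectra(rng, [(0, "Fz"), (0, "F3"), (0, "F4")])
        with pytest.raises(ProcessingError, match="s00"):
            impute_channels(table)


def perm_inputs(rng, n=30, n_e=4, seed_shift=0.0):
    electrodes = ["F3", "Fz", "F4", "Cz"][:n_e]
    table = random_spectra(rng, n_subjects=n, electrodes=electrodes)
    res = rng.normal(20, 5, n) + seed_shift
    age = rng.uniform(20, 60, n)
    return table, res, age


class TestPermutation:
    def test_reproducible_with_seed(self, rng):
        table, res, age = perm_inputs(rng)
        a = permutation_correct(table, res, age, n_perm=200, seed=42)
        b = permutation_correct(table, res, age, n_perm=200, seed=42)
        assert np.array_equal(a.p_corr, b.p_corr)

    def test_seed_required_in_strict_mode(self, rng):
        table, res, age = perm_inputs(rng)
        with pytest.raises(ValidationError, match="seed"):
            permutation_correct(table, res, age, n_perm=200)

    def test_perfect_correlation_hits_floor(self, rng):
        table, res, age = perm_inputs(rng, n=30)
        n_perm = 500
        res = table.values[:, 1, 40].copy()  # trait == one cell's values
        out = permutation_correct(table, res, age, n_perm=n_perm, seed=7)
        assert out.p_corr[1, 40] == pytest.approx(1.0 / (n_perm + 1))
        assert out.r_obs[1, 40] == pytest.approx(1.0)

    def test_corrected_p_bounds(self, rng):
        table, res, age = perm_inputs(rng)
        out = permutation_correct(table, res, age, n_perm=300, seed=3)
        assert np.all(out.p_corr >= 1 / 301)
        assert np.all(out.p_corr <= 1.0)

    def test_monotone_in_observed_r(self, rng):
        table, res, age = perm_inputs(rng)
        out = permutation_correct(table, res, age, n_perm=300, seed=3,
                                  family="bin")
        for bi in range(0, 157, 13):
            order = np.argsort(np.abs(out.r_obs[:, bi]))
            ps = out.p_corr[order, bi]
            assert np.all(np.diff(ps) <= 1e-12)

    def test_grid_family_never_less_strict(self, rng):
        table, res, age = perm_inputs(rng)
        by_bin = permutation_correct(table, res, age, n_perm=400, seed=9,
                                     family="bin")
        by_grid = permutation_correct(table, res, age, n_perm=400, seed=9,
                                      family="grid")
        assert np.all(by_grid.p_corr >= by_bin.p_corr - 1e-12)

    def test_missing_data_rejected(self, rng):
        table, res, age = perm_inputs(rng)
        table.values[0, 0] = np.nan
        with pytest.raises(ValidationError, match="impute"):
            permutation_correct(table, res, age, n_perm=100, seed=1)


class TestSignificantRanges:
    def _perm_result(self, p):
        p = np.asarray(p, float)
        return PermResult(electrodes=[f"E{i}" for i in range(p.shape[0])],
                          bins=FREQ_BINS[:p.shape[1]], p_corr=p,
                          r_obs=np.zeros_like(p), n_perm=100, family="bin",
                          seed=0)

    def test_multichannel_range_reported(self):
        p = np.ones((8, 20))
        p[:7, 9:16] = 0.01  # 3.25-4.75 Hz on 7 channels
        ranges = summarize_significant_ranges(self._perm_result(p))
        assert len(ranges) == 1
        assert (ranges[0].first_hz, ranges[0].last_hz) == (3.25, 4.75)
        assert ranges[0].channels == [f"E{i}" for i in range(7)]

    def test_single_channel_range_dropped(self):
        p = np.ones((8, 20))
        p[3, 5:10] = 0.01
        assert summarize_significant_ranges(self._perm_result(p)) == []

    def test_no_significance_empty(self):
        p = np.ones((4, 20))
        assert summarize_significant_ranges(self._perm_result(p)) == []
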
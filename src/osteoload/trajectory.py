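"""Normalized-distance processing of per-trial moment curves.

Machine travel is rescaled to a normalized distance s in [0, 1] over each
trial's range of motion.  Fingertip-to-palm trials (test 1) are analyzed
over the full range; wrist-flexion trials (test 2) only over the first
half of travel (the second half overextends natural flexion), and the
analyzed half-window is re-normalized onto the same 0-1 reporting grid.
Curves are resampled by linear interpolation onto the six-step grid
{0, 0.2, ..., 1}; per-trial maxima are taken on the raw analyzed window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REPORT_GRID",
    "TrialRecord",
    "CohortSummary",
    "normalize_and_window",
    "resample_grid",
    "select_trials",
    "summarize_cohort",
]

REPORT_GRID = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])

#: trials retained for analysis (1-based indices; earlier trials absorb
#: setup artifacts)
RETAINED_TRIALS = (3, 4, 5)


@dataclass
class TrialRecord:
    """One digit/test/trial with its raw and processed moment curve."""

    hand: int
    digit: int
    test: int
    trial: int
    travel: np.ndarray  # machine travel, mm
    moment: np.ndarray  # |Mz| at the cut plane, N*mm
    normalized: np.ndarray | None = None  # (s, moment) after windowing
    max_moment: float | None = None

    def process(self, half_window_renormalized: bool = True) -> "TrialRecord":
        s, m = normalize_and_window(
            np.column_stack([self.travel, self.moment]),
            self.test,
            half_window_renormalized=half_window_renormalized,
        )
        self.normalized = np.column_stack([s, m])
        self.max_moment = float(m.max())
        return self

    def grid_moments(self, grid: np.ndarray = REPORT_GRID) -> np.ndarray:
        if self.normalized is None:
            self.process()
        return resample_grid(self.normalized, grid)


def normalize_and_window(
    samples: np.ndarray,
    test: int,
    half_window_renormalized: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize travel to [0, 1] and apply the per-test analysis window.

    ``samples`` is (n, 2): travel (nondecreasing, mm) and moment.  For
    test 2 only s <= 0.5 is analyzed; with ``half_window_renormalized``
    (the default) the retained half is re-indexed onto [0, 1] so that the
    reporting grid spans the analyzed window.  With the flag off, grid
    step 1 of a test-2 trial corresponds to the half-travel point and the
    grid is left on the original scale 0-0.5.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or len(samples) < 2:
        raise ValueError("need an (n>=2, 2) array of (travel, moment) samples")
    travel, moment = samples[:, 0], samples[:, 1]
    if np.any(np.diff(travel) < -1e-12):
        raise ValueError("travel must be nondecreasing")
    span = travel[-1] - travel[0]
    if span <= 0:
        raise ValueError("zero total travel: cannot normalize")
    s = (travel - travel[0]) / span
    if test == 2:
        keep = s <= 0.5 + 1e-12
        s, moment = s[keep], moment[keep]
        if len(s) < 2:
            raise ValueError("fewer than 2 samples in the analyzed half-window")
        if half_window_renormalized:
            s = s / s[-1]
    elif test != 1:
        raise ValueError(f"test must be 1 or 2, got {test}")
    return s, moment


def resample_grid(
    normalized: np.ndarray, grid: np.ndarray = REPORT_GRID
) -> np.ndarray:
    """Linear interpolation of a normalized curve onto the reporting grid.

    Exact sample values are reused where s coincides with a grid point;
    extrapolation is an error.
    """
    normalized = np.asarray(normalized, dtype=float)
    s, m = normalized[:, 0], normalized[:, 1]
    grid = np.asarray(grid, dtype=float)
    if grid.min() < s.min() - 1e-12 or grid.max() > s.max() + 1e-12:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] extends beyond the curve "
            f"support [{s.min()}, {s.max()}]: extrapolation forbidden"
        )
    return np.interp(grid, s, m)


def select_trials(trials: Sequence[int], retained: Sequence[int] = RETAINED_TRIALS) -> list[int]:
    """Apply the retained-trials rule to recorded trial indices.

    Requires the full protocol (at least 5 recorded trials); extra trials
    beyond 5 are ignored with a warning.
    """
    trials = sorted(trials)
    if len(trials) < 5:
        raise ValueError(
            f"incomplete digit: {len(trials)} trials recorded, protocol needs 5"
        )
    if len(trials) > 5:
        warnings.warn(f"{len(trials)} trials recorded; retaining {tuple(retained)} only")
    missing = set(retained) - set(trials)
    if missing:
        raise ValueError(f"retained trials {sorted(missing)} not recorded")
    return [t for t in trials if t in set(retained)]


@dataclass
class CohortSummary:
    """Grouped step-wise means/SDs and pooled per-trial maxima."""

    table: pd.DataFrame  # rows: grid step; columns: (test, digit, mean|sd)
    maxima: pd.DataFrame  # one row per trial: hand, digit, test, trial, max_moment
    group_sizes: dict[tuple[int, int], int]
    flags: list[str] = field(default_factory=list)

    def group_maxima(self, test: int, digit: int) -> np.ndarray:
        m = self.maxima
        sel = (m["test"] == test) & (m["digit"] == digit)
        return m.loc[sel, "max_moment"].to_numpy()

    def to_csv(self, table_path, maxima_path) -> None:
        self.table.to_csv(table_path)
        self.maxima.to_csv(maxima_path, index=False)


def summarize_cohort(
    records: Iterable[TrialRecord],
    grid: np.ndarray = REPORT_GRID,
    sd_convention: Literal["sample", "population"] = "sample",
) -> CohortSummary:
    """Per-(test, digit) mean +/- SD at each grid step and pooled maxima.

    Step-0 entries are exactly 0 +/- 0 by construction (every trial starts
    unloaded).  Single-record groups get SD 0 with a flag.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    rows = []
    for r in records:
        g = r.grid_moments(grid)
        rows.append(
            dict(hand=r.hand, digit=r.digit, test=r.test, trial=r.trial,
                 max_moment=r.max_moment, **{f"s{si}": gi for si, gi in zip(grid, g)})
        )
    df = pd.DataFrame(rows)
    flags = []
    ddof = 1 if sd_convention == "sample" else 0
    cols = {}
    sizes = {}
    for (test, digit), grp in df.groupby(["test", "digit"]):
        sizes[(int(test), int(digit))] = len(grp)
        vals = grp[[f"s{si}" for si in grid]].to_numpy()
        mean = vals.mean(axis=0)
        if len(grp) > ddof:
            sd = vals.std(axis=0, ddof=ddof)
        else:
            sd = np.zeros(vals.shape[1])
            flags.append(f"test {test} digit {digit}: single record, SD reported as 0")
        cols[(int(test), int(digit), "mean")] = mean
        cols[(int(test), int(digit), "sd")] = sd
    table = pd.DataFrame(cols, index=pd.Index(grid, name="step"))
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["test", "digit", "stat"])
    maxima = df[["hand", "digit", "test", "trial", "max_moment"]].copy()
    return CohortSummary(table=table, maxima=maxima, group_sizes=sizes, flags=flags)
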
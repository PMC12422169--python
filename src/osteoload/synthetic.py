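"""Synthetic trial trajectories and study cohorts.

The cadaveric experiment this pipeline mirrors drove each digit through a
rehabilitation motion while tracking the bone fragments optically; the
fragment motion, replayed through a finite-element model of the fixation,
yields the internal loads.  Here that measurement chain is replaced by a
parametric generator:

* a **displacement pattern** — the rigid motion of the distal fragment per
  mm of "machine travel": rotation about the flexion (z) axis through the
  plate mid-surface at the gap center, with a small transverse translation
  coupling.  The plate is the only load path across the gap, so it acts as
  the construct's neutral element and relative flexion hinges about it;
* a **trajectory template** per digit and test — a monotone displacement-
  amplitude profile over normalized travel whose forward-solved moment
  curve has the reported shape (exponential-like rise for fingertip-to-
  palm, rise-then-plateau for wrist flexion) and magnitude;
* a **cohort design** — hands x digits x trials with retained-trial and
  exclusion rules, defaulting to the five-donor roster.

Noise model: a multiplicative log-normal between-hand (specimen) effect,
shared by all digits of a hand, times an additive Gaussian between-trial
perturbation of the amplitude scale.  Both are expressed in moment units
(N*mm) at the template's peak so generated cohorts have standard
deviations on the scale of the benchmark tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .geometry import ConstructGeometry
from .trajectory import REPORT_GRID

__all__ = [
    "DisplacementPattern",
    "TrajectoryTemplate",
    "TrialPath",
    "CohortDesign",
    "TrialInput",
    "default_cohort_design",
    "make_trajectory",
    "calibrate_template",
    "generate_cohort",
    "exponential_profile",
    "plateau_profile",
    "REFERENCE_MOMENT_TARGETS",
    "REFERENCE_MOMENT_SDS",
    "default_templates",
]

# ---------------------------------------------------------------------------
# benchmark moment levels (N*mm) on the six-step reporting grid: cadaveric
# bending-moment magnitudes for metacarpal plate fixation during
# fingertip-to-palm (test 1) and wrist-flexion (test 2) rehabilitation
# motion, per digit.  Used as calibration targets for the generator.
# ---------------------------------------------------------------------------
REFERENCE_MOMENT_TARGETS: dict[tuple[int, int], tuple[float, ...]] = {
    (1, 2): (0.0, 0.25, 0.49, 1.39, 4.09, 8.57),
    (1, 3): (0.0, 0.09, 0.29, 0.76, 1.56, 4.71),
    (1, 4): (0.0, 0.19, 0.92, 1.69, 2.53, 4.88),
    (2, 2): (0.0, 0.65, 2.26, 3.56, 4.25, 4.77),
    (2, 3): (0.0, 0.42, 1.67, 2.59, 3.03, 2.98),
    (2, 4): (0.0, 0.24, 0.83, 1.38, 1.86, 2.13),
}
REFERENCE_MOMENT_SDS: dict[tuple[int, int], tuple[float, ...]] = {
    (1, 2): (0.0, 0.23, 0.80, 1.08, 0.75, 1.06),
    (1, 3): (0.0, 0.13, 0.26, 0.59, 1.30, 1.02),
    (1, 4): (0.0, 0.22, 0.72, 0.68, 1.22, 0.51),
    (2, 2): (0.0, 0.46, 1.30, 1.67, 1.45, 1.34),
    (2, 3): (0.0, 0.25, 0.64, 0.82, 0.96, 1.42),
    (2, 4): (0.0, 0.18, 0.48, 0.61, 0.69, 0.68),
}


@dataclass(frozen=True)
class DisplacementPattern:
    """Rigid motion of the distal fragment per mm of travel amplitude.

    ``rotation_per_travel`` (deg/mm) is a linearized rotation about the
    z-axis through ``rotation_center``; ``translation_per_travel`` (mm/mm)
    adds a transverse coupling.  The default center — plate mid-surface at
    the gap center — produces gap-opening flexion with dorsal-fiber
    tension in the plate.
    """

    rotation_center: tuple[float, float, float]
    rotation_per_travel: float = -0.5
    translation_per_travel: tuple[float, float, float] = (0.0, -0.05, 0.0)

    @classmethod
    def for_geometry(cls, geometry: ConstructGeometry, **kw) -> "DisplacementPattern":
        c = (0.0, geometry.plate_bottom + geometry.plate_thickness / 2.0, 0.0)
        return cls(rotation_center=c, **kw)

    def displacements(self, nodes: np.ndarray, amplitude: float = 1.0) -> np.ndarray:
        """Prescribed displacement vectors for the given nodes (n, 3)."""
        theta = math.radians(self.rotation_per_travel) * amplitude
        r = nodes - np.asarray(self.rotation_center)
        u = theta * np.cross([0.0, 0.0, 1.0], r)
        return u + amplitude * np.asarray(self.translation_per_travel)


def exponential_profile(peak: float, steepness: float = 3.0) -> np.ndarray:
    """Amplitudes on the reporting grid with an exponential-like rise
    (strictly convex, 0 at the start) reaching ``peak`` at s = 1."""
    s = REPORT_GRID
    return peak * (np.exp(steepness * s) - 1.0) / (math.exp(steepness) - 1.0)


def plateau_profile(peak: float, rate: float = 4.0) -> np.ndarray:
    """Amplitudes rising then saturating (wrist-flexion shape)."""
    s = REPORT_GRID
    return peak * (1.0 - np.exp(-rate * s)) / (1.0 - math.exp(-rate))


@dataclass(frozen=True)
class TrajectoryTemplate:
    """Monotone displacement-amplitude profile with its noise parameters.

    ``amplitudes`` are travel-amplitude values (mm) at the six-step grid;
    intermediate values come from monotone (PCHIP) interpolation.  Noise
    scales are stated in moment units (N*mm) relative to
    ``peak_moment_target`` so they are comparable with reported SDs.
    """

    test_id: int
    amplitudes: tuple[float, ...]
    peak_moment_target: float
    noise_sd: float = 0.0
    specimen_effect_sd: float = 0.0
    unit_moment: float | None = None  # N*mm per mm amplitude (calibration)
    grid: tuple[float, ...] | None = None  # raw-travel knots; default report grid

    def __post_init__(self) -> None:
        if self.grid is None:
            object.__setattr__(self, "grid", tuple(REPORT_GRID))
        grid = np.asarray(self.grid, float)
        amp = np.asarray(self.amplitudes, float)
        if len(amp) != len(grid):
            raise ValueError("amplitudes and grid must have equal length")
        if abs(grid[0]) > 1e-12 or abs(grid[-1] - 1.0) > 1e-12 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must increase strictly from 0 to 1")
        if abs(amp[0]) > 1e-12:
            raise ValueError("displacement profile must start at 0")
        if np.any(np.diff(amp) < -1e-12):
            raise ValueError("displacement profile must be nondecreasing in travel")
        if self.peak_moment_target <= 0 and np.any(amp > 0):
            raise ValueError("peak_moment_target must be positive")
        if self.test_id not in (1, 2):
            raise ValueError("test_id must be 1 or 2")

    def profile(self, s: np.ndarray) -> np.ndarray:
        amp = np.asarray(self.amplitudes, float)
        if np.all(amp == 0):
            return np.zeros_like(np.asarray(s, float))
        return PchipInterpolator(np.asarray(self.grid, float), amp)(s)

    @property
    def relative_specimen_sd(self) -> float:
        if self.peak_moment_target <= 0:
            return 0.0
        return self.specimen_effect_sd / self.peak_moment_target


@dataclass
class TrialPath:
    """One trial's prescribed displacement path over machine travel."""

    s: np.ndarray  # normalized travel in [0, 1]
    travel: np.ndarray  # machine travel, mm
    amplitude: np.ndarray  # displacement amplitude, mm (nondecreasing)
    template: TrajectoryTemplate

    def __len__(self) -> int:
        return len(self.s)


def make_trajectory(
    template: TrajectoryTemplate,
    hand_effect: float = 0.0,
    seed: int = 0,
    n_samples: int = 41,
    travel_span: float = 10.0,
) -> TrialPath:
    """Sample a per-trial displacement path from a template.

    ``hand_effect`` is the specimen's log-scale effect (0 gives the
    template exactly when ``noise_sd`` is 0); the trial-level perturbation
    is an additive Gaussian on the amplitude scale, expressed through the
    template's moment units.  Same seed => bit-identical path.
    """
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, 1.0, n_samples)
    base = template.profile(s)
    factor = math.exp(hand_effect)
    if template.noise_sd > 0 and template.peak_moment_target > 0:
        factor = factor + rng.normal(0.0, template.noise_sd) / template.peak_moment_target
    factor = max(factor, 0.05)  # keep the path monotone-forward
    amp = factor * base
    return TrialPath(s=s, travel=s * travel_span, amplitude=amp, template=template)


def calibrate_template(
    geometry: ConstructGeometry | None,
    materials=None,
    target_curve: Sequence[float] | None = None,
    test_id: int = 1,
    unit_moment: float | None = None,
    mesh_params=None,
    noise_sd: float = 0.0,
    specimen_effect_sd: float = 0.0,
    rel_tol: float = 0.02,
) -> TrajectoryTemplate:
    """Invert the (linear) forward model so the template's forward-solved
    moment curve reproduces ``target_curve`` on the reporting grid.

    For a linear-elastic construct the cut-plane moment scales with the
    displacement amplitude, so per-step root finding reduces to division
    by the unit moment (one solve per unit amplitude).  Non-monotone
    targets get a running-maximum repair of the implied amplitudes; the
    repair must stay within ``rel_tol`` of the target or calibration
    fails.  Pass ``unit_moment`` to reuse an existing solve.

    ``target_curve`` lives on the reporting grid of the *analyzed window*:
    for test 2 (wrist flexion) that window is the first half of travel, so
    the template knots are placed at raw travel s/2 and the profile is
    extended beyond s = 0.5 at half its final slope (that part of the
    motion overextends natural flexion and is excluded from analysis).
    """
    target = np.asarray(target_curve, float)
    if len(target) != len(REPORT_GRID):
        raise ValueError(f"target_curve needs {len(REPORT_GRID)} grid values")
    if abs(target[0]) > 1e-12 or np.any(target < 0):
        raise ValueError("target curve must be nonnegative and start at 0")
    if np.all(target == 0):
        return TrajectoryTemplate(
            test_id=test_id, amplitudes=(0.0,) * len(REPORT_GRID),
            peak_moment_target=1.0, noise_sd=noise_sd,
            specimen_effect_sd=specimen_effect_sd, unit_moment=unit_moment,
        )
    if unit_moment is None:
        from .pipeline import unit_cut_moment  # lazy: avoids module cycle

        unit_moment = unit_cut_moment(geometry, materials, mesh_params)
    if unit_moment <= 0:
        raise ValueError(
            "target unreachable: unit displacement produces no positive moment"
        )
    amps = target / unit_moment
    repaired = np.maximum.accumulate(amps)
    achieved = repaired * unit_moment
    nz = target > 0
    if np.any(np.abs(achieved[nz] - target[nz]) / target[nz] > rel_tol):
        raise ValueError(
            "target unreachable with a monotone positive-displacement path "
            f"within {rel_tol:.0%}"
        )
    if test_id == 2:
        # analyzed half-window: knots at raw s/2, mild continuation to s=1
        grid = tuple(REPORT_GRID / 2.0) + (1.0,)
        slope = (repaired[-1] - repaired[-2]) / (REPORT_GRID[-1] - REPORT_GRID[-2]) * 2.0
        tail = repaired[-1] + 0.5 * slope * 0.5
        amplitudes = tuple(repaired) + (float(tail),)
    else:
        grid = tuple(REPORT_GRID)
        amplitudes = tuple(repaired)
    return TrajectoryTemplate(
        test_id=test_id,
        amplitudes=amplitudes,
        peak_moment_target=float(target.max()),
        noise_sd=noise_sd,
        specimen_effect_sd=specimen_effect_sd,
        unit_moment=float(unit_moment),
        grid=grid,
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HandInfo:
    side: str
    sex: str
    age: float
    height_cm: float
    weight_kg: float
    bmi: float


#: five-donor roster (hand id -> covariates)
DEFAULT_HANDS: dict[int, HandInfo] = {
    1: HandInfo("Left", "Male", 41, 170.2, 82.1, 28.4),
    2: HandInfo("Right", "Male", 41, 170.2, 82.1, 28.4),
    3: HandInfo("Right", "Male", 50, 180.3, 95.3, 29.3),
    4: HandInfo("Right", "Male", 47, 170.2, 78.9, 27.3),
    5: HandInfo("Right", "Male", 34, 182.9, 87.1, 26.5),
}


@dataclass(frozen=True)
class CohortDesign:
    """Hands x digits x trials structure with retention and exclusions."""

    hands: Mapping[int, HandInfo]
    digits: tuple[int, ...] = (2, 3, 4)
    trials_per_digit: int = 5
    retained_trials: tuple[int, ...] = (3, 4, 5)
    exclusions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        bad = [t for t in self.retained_trials if not 1 <= t <= self.trials_per_digit]
        if bad:
            raise ValueError(f"retained trials {bad} outside 1..{self.trials_per_digit}")
        for hand, digit in self.exclusions:
            if hand not in self.hands or digit not in self.digits:
                raise ValueError(f"exclusion ({hand}, {digit}) references unknown hand/digit")

    def units(self) -> list[tuple[int, int]]:
        """(hand, digit) pairs that actually produce data."""
        excl = set(self.exclusions)
        return [
            (h, d)
            for h in self.hands
            for d in self.digits
            if (h, d) not in excl
        ]

    def group_size(self, digit: int) -> int:
        excl = sum(1 for _, d in self.exclusions if d == digit)
        return (len(self.hands) - excl) * len(self.retained_trials)


def default_cohort_design() -> CohortDesign:
    """Five hands, digits 2-4, five trials with 3-5 retained, and the
    fourth digit of hand 2 excluded (severed flexor tendon), giving
    per-digit group sizes 15 / 15 / 12."""
    return CohortDesign(hands=DEFAULT_HANDS, exclusions=((2, 4),))


@dataclass
class TrialInput:
    """Generated inputs of one retained trial (moments filled downstream)."""

    hand: int
    digit: int
    test: int
    trial: int
    path: TrialPath
    hand_info: HandInfo | None = None


def default_templates(
    unit_moment: float,
    noise_scale: float = 1.0,
) -> dict[tuple[int, int], TrajectoryTemplate]:
    """Templates calibrated to the benchmark moment levels for every
    (test, digit), with specimen/trial noise split 0.8/0.6 of the reported
    peak-step SD (so total SD matches; scaled by ``noise_scale``)."""
    out = {}
    for (test, digit), target in REFERENCE_MOMENT_TARGETS.items():
        sds = REFERENCE_MOMENT_SDS[(test, digit)]
        peak_step = int(np.argmax(target))
        sd_peak = sds[peak_step]
        out[(test, digit)] = calibrate_template(
            None,
            None,
            target_curve=target,
            test_id=test,
            unit_moment=unit_moment,
            noise_sd=0.6 * sd_peak * noise_scale,
            specimen_effect_sd=0.8 * sd_peak * noise_scale,
        )
    return out


def generate_cohort(
    design: CohortDesign,
    templates: Mapping[tuple[int, int], TrajectoryTemplate],
    seed: int = 0,
    n_samples: int = 41,
) -> list[TrialInput]:
    """Generate all retained-trial inputs for a cohort.

    One record per (hand, digit, test, retained trial), excluding the
    design's exclusions.  The specimen effect is a single standard-normal
    draw per hand, scaled by each template's relative specimen SD, so a
    globally stiff or lax hand is consistent across its digits and tests.
    Trial-level seeds descend deterministically from ``seed``.
    """
    if not design.hands:
        return []
    hand_ids = sorted(design.hands)
    hand_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    z_hand = dict(zip(hand_ids, hand_rng.standard_normal(len(hand_ids))))
    records: list[TrialInput] = []
    tests = sorted({t for (t, _) in templates})
    for test in tests:
        for hand, digit in design.units():
            tmpl = templates.get((test, digit))
            if tmpl is None:
                raise KeyError(f"no template for test {test}, digit {digit}")
            sigma_rel = tmpl.relative_specimen_sd
            # log-normal with unit median; z shared across the hand
            hand_effect = z_hand[hand] * sigma_rel
            for trial in design.retained_trials:
                rec_seed = int(
                    np.random.SeedSequence(
                        entropy=seed, spawn_key=(test, hand, digit, trial)
                    ).generate_state(1)[0] % (2**31)
                )
                path = make_trajectory(
                    tmpl, hand_effect=hand_effect, seed=rec_seed, n_samples=n_samples
                )
                records.append(
                    TrialInput(
                        hand=hand, digit=digit, test=test, trial=trial,
                        path=path, hand_info=design.hands[hand],
                    )
                )
    return records
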
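"""Synthetic data with the statistical structure the analysis assumes.

Two generators mirror the two arms of the pipeline:

* ``simulate_rat_experiment`` — multi-study isoeffect experiments.  Each
  simulated data set receives one multiplicative calibration factor (the
  between-study dosimetry/quality-factor error the normalization step is
  meant to remove) and every D50 an additional residual error; both are
  lognormal so doses stay positive and errors act multiplicatively.
* ``simulate_cohorts`` — binomial myelopathy cohorts drawn from a known
  logistic-BED truth, on an arbitrary design of (course, total) pairs.

Both are deterministic given their seed, and both emit the same objects the
packaged tables load into, so simulated data flow through the identical
pipeline (CSV round-trip included).

Default configurations reproduce the designs of the packaged tables: the six
rat fractionation schedules, and the combined large-animal + human cohort
design with truth (α/β, BED50, k) = (3.9 Gy, 111 Gy, 10.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datasets import D50Point, RatDataset, RIMCohort, group_cohorts, load_cohort_table, load_rat_table
from .lq import LQParameters, TreatmentCourse, bed_of_course, dose_for_bed_at_n
from .rim import prim_from_bed

__all__ = [
    "RatSimConfig",
    "CohortSimConfig",
    "simulate_rat_experiment",
    "simulate_cohorts",
    "table_schedules",
    "table_design",
]


def table_schedules() -> List[Tuple[str, str, List[int]]]:
    """(label, site, fraction numbers) of the six packaged rat datasets."""
    return [
        (ds.study_label, ds.site, [p.n_fractions for p in ds.points])
        for ds in load_rat_table()
    ]


def table_design(group: str = "D") -> List[Tuple[TreatmentCourse, int]]:
    """(course, total) design of a packaged cohort group (corrected table)."""
    return [(c.course, c.total) for c in group_cohorts(load_cohort_table(), group)]


@dataclass
class RatSimConfig:
    """Truth and noise levels for a simulated multi-study rat experiment.

    ``calibration_cv`` is the coefficient of variation of the per-dataset
    multiplicative dose-calibration factor — the between-study error that
    motivates single-fraction normalization.  ``residual_cv`` is the
    per-point CV of the D50 estimate itself (sampling error of the 50%
    isoeffect dose within one experiment; 5% is typical of quantal
    dose-response assays with group sizes of 5-10 animals).
    """

    alpha_beta: float = 4.1
    bed50: float = 119.0
    schedules: Optional[List[Tuple[str, str, List[int]]]] = None
    calibration_cv: float = 0.10
    residual_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha_beta, self.bed50) <= 0:
            raise ValueError("truth parameters must be positive")
        if self.calibration_cv < 0 or self.residual_cv < 0:
            raise ValueError("noise CVs must be non-negative")
        if self.schedules is None:
            self.schedules = table_schedules()


@dataclass
class CohortSimConfig:
    """Truth and design for simulated binomial myelopathy cohorts."""

    alpha_beta: float = 3.9
    bed50: float = 111.0
    k: float = 10.5
    design: Optional[List[Tuple[TreatmentCourse, int]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha_beta, self.bed50, self.k) <= 0:
            raise ValueError("truth parameters must be positive")
        if self.design is None:
            self.design = table_design("D")
        for _, total in self.design:
            if total < 1:
                raise ValueError("cohort totals must be >= 1")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Unit-median lognormal multiplier with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def simulate_rat_experiment(config: RatSimConfig) -> List[RatDataset]:
    """Draw one multi-study isoeffect experiment from a known LQ truth.

    For each dataset: exact D50(n) from the truth via the positive-root
    isoeffect solution, times one shared calibration factor, times a
    per-point residual factor.  Zero noise reproduces the truth exactly.
    """
    rng = np.random.default_rng(config.seed)
    params = LQParameters(config.alpha_beta)
    out = []
    for label, site, fractions in config.schedules:
        calib = float(_lognormal_factor(rng, config.calibration_cv))
        resid = _lognormal_factor(rng, config.residual_cv, size=len(fractions))
        points = []
        for n, r in zip(fractions, np.atleast_1d(resid)):
            exact = dose_for_bed_at_n(config.bed50, n, params)
            points.append(D50Point(exact * calib * float(r), n))
        out.append(
            RatDataset(study_label=label, site=site, follow_up_days=365.0, points=tuple(points))
        )
    return out


def simulate_cohorts(config: CohortSimConfig) -> List[RIMCohort]:
    """Draw binomial myelopathy cohorts from a known logistic-BED truth."""
    rng = np.random.default_rng(config.seed)
    params = LQParameters(config.alpha_beta)
    out = []
    for i, (course, total) in enumerate(config.design):
        p = prim_from_bed(bed_of_course(course, params), config.bed50, config.k)
        events = int(rng.binomial(total, p))
        out.append(
            RIMCohort(
                study_label=f"sim-{i:03d}",
                species="human",
                site="mixed",
                events=events,
                total=total,
                course=course,
            )
        )
    return out
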
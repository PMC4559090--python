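"""Linear-quadratic / biologically-effective-dose arithmetic.

The linear-quadratic (LQ) model summarises the fractionation sensitivity of a
tissue by the ratio α/β (Gy).  A course delivering ``n`` fractions of ``d`` Gy
has a biologically effective dose

    BED = n · d · (1 + d / (α/β))          [Gy]

and two courses with equal BED are predicted to be isoeffective regardless of
how the dose was fractionated.  Courses that chain several fractionation
regimens accumulate BED additively over the regimens.

This module provides the forward BED computation together with the inverse
solves used for isoeffective-dose conversion: total dose at a fixed dose per
fraction (the EQD-style conversion), and total dose at a fixed number of
fractions, which is the positive root of the quadratic

    D²/(n · α/β) + D − BED = 0.

All doses are in Gy and treated as continuous; rounding to one decimal is a
reporting concern, not a modelling one.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Tuple

__all__ = [
    "FractionationRegimen",
    "TreatmentCourse",
    "LQParameters",
    "bed_of_course",
    "total_dose_for_bed",
    "dose_for_bed_at_n",
    "parse_course",
    "format_course",
]


@dataclass(frozen=True)
class FractionationRegimen:
    """A block of ``n_fractions`` identical fractions of ``dose_per_fraction`` Gy."""

    dose_per_fraction: float
    n_fractions: int

    def __post_init__(self) -> None:
        if not self.dose_per_fraction > 0:
            raise ValueError(
                f"dose_per_fraction must be > 0 Gy, got {self.dose_per_fraction}"
            )
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValueError(f"n_fractions must be a positive integer, got {self.n_fractions}")

    @property
    def total_dose(self) -> float:
        return self.dose_per_fraction * self.n_fractions


@dataclass(frozen=True)
class TreatmentCourse:
    """An ordered, non-empty sequence of fractionation regimens.

    BED is additive over the regimens, so a split-course treatment such as
    ``6 Gy × 3 + 4 Gy × 5`` is represented exactly as delivered.
    """

    regimens: Tuple[FractionationRegimen, ...]

    def __post_init__(self) -> None:
        regimens = tuple(self.regimens)
        if len(regimens) < 1:
            raise ValueError("a treatment course needs at least one regimen")
        object.__setattr__(self, "regimens", regimens)

    @classmethod
    def single(cls, dose_per_fraction: float, n_fractions: int) -> "TreatmentCourse":
        return cls((FractionationRegimen(dose_per_fraction, n_fractions),))

    @classmethod
    def from_string(cls, text: str) -> "TreatmentCourse":
        return parse_course(text)

    @property
    def total_dose(self) -> float:
        return sum(r.total_dose for r in self.regimens)

    def __str__(self) -> str:
        return format_course(self)


@dataclass(frozen=True)
class LQParameters:
    """LQ fractionation-sensitivity parameter α/β in Gy (strictly positive)."""

    alpha_beta: float

    def __post_init__(self) -> None:
        if not self.alpha_beta > 0:
            raise ValueError(f"alpha_beta must be > 0 Gy, got {self.alpha_beta}")


def bed_of_course(course: TreatmentCourse, params: LQParameters) -> float:
    """Biologically effective dose of a (possibly multi-regimen) course.

    BED = Σᵢ nᵢ·dᵢ·(1 + dᵢ/(α/β)), summed over the course's regimens.
    """
    ab = params.alpha_beta
    return sum(
        r.n_fractions * r.dose_per_fraction * (1.0 + r.dose_per_fraction / ab)
        for r in course.regimens
    )


def total_dose_for_bed(bed: float, dose_per_fraction: float, params: LQParameters) -> float:
    """Total dose delivering ``bed`` at a fixed dose per fraction.

    D = BED / (1 + d/(α/β)).  The fraction count D/d is treated as continuous,
    matching the convention of isoeffective-dose tables.
    """
    if bed < 0:
        raise ValueError(f"bed must be >= 0 Gy, got {bed}")
    if not dose_per_fraction > 0:
        raise ValueError(f"dose_per_fraction must be > 0 Gy, got {dose_per_fraction}")
    return bed / (1.0 + dose_per_fraction / params.alpha_beta)


def dose_for_bed_at_n(bed: float, n_fractions: int, params: LQParameters) -> float:
    """Total dose delivering ``bed`` in exactly ``n_fractions`` fractions.

    Solves D²/(n·α/β) + D − BED = 0 for the positive root:

        D = [ −n·α/β + sqrt( n²·(α/β)² + 4·n·α/β·BED ) ] / 2

    In the many-fraction limit the quadratic term vanishes and D → BED.
    """
    if bed < 0:
        raise ValueError(f"bed must be >= 0 Gy, got {bed}")
    if n_fractions < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n_fractions}")
    nab = n_fractions * params.alpha_beta
    return (-nab + math.sqrt(nab * nab + 4.0 * nab * bed)) / 2.0


_REGIMEN_RE = re.compile(r"^\s*([0-9]*\.?[0-9]+)\s*[x×]\s*([0-9]+)\s*$")


def parse_course(text: str) -> TreatmentCourse:
    """Parse the ``"<d>x<n>"`` course grammar, regimens joined by ``+``.

    Examples: ``"2x30"``, ``"6x3+4x5"``, mirroring the ``6 × 3 + 4 × 5``
    notation of split-course prescriptions.
    """
    parts = text.split("+")
    regimens = []
    for part in parts:
        m = _REGIMEN_RE.match(part)
        if m is None:
            raise ValueError(f"malformed course regimen {part!r} in {text!r}")
        regimens.append(FractionationRegimen(float(m.group(1)), int(m.group(2))))
    return TreatmentCourse(tuple(regimens))


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def format_course(course: TreatmentCourse) -> str:
    """Inverse of :func:`parse_course` (lossless for float doses)."""
    return "+".join(
        f"{_fmt_num(r.dose_per_fraction)}x{r.n_fractions}" for r in course.regimens
    )
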
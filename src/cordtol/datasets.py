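"""Packaged myelopathy isoeffect and incidence tables, with readers and writers.

Two compilations ship with the package as plain CSV:

* a rat isoeffect table — six data sets from five fractionation experiments,
  each a list of (D50, n) points: the total dose producing 50% incidence of
  radiation-induced myelopathy (RIM) when delivered in n fractions;
* a cohort incidence table — large-animal (dog, monkey, pig) and human cohorts,
  each a binomial outcome (events / total) attached to a treatment course.

The cohort table is stored exactly as originally reported.  Three documented
data problems (a cord-dose re-estimate, a misquoted denominator, and one
unverifiable cohort) are kept in a separate machine-readable corrections
ledger and applied on load; ``apply_corrections=False`` returns the
uncorrected transcription so the effect of every correction is auditable.

Analysis groups follow the compilation's convention:
A = rats, B = large animals, C = humans, D = B ∪ C.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Sequence

from .lq import TreatmentCourse, format_course, parse_course

__all__ = [
    "D50Point",
    "RatDataset",
    "RIMCohort",
    "CorrectionLedgerEntry",
    "load_rat_table",
    "load_cohort_table",
    "load_corrections",
    "apply_ledger",
    "group_cohorts",
    "read_rat_csv",
    "write_rat_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "FixtureIntegrityError",
]

RAT_SITES = {"cervical", "thoracic", "lumbar"}
COHORT_SITES = {"cervical", "thoracic", "mixed"}
SPECIES = {"dog", "monkey", "pig", "human"}

#: Cord-site subgroups used throughout the rat analysis.
CERVICAL_SUBGROUP = "cervical"
THORACOLUMBAR_SUBGROUP = "thoracolumbar"


class FixtureIntegrityError(RuntimeError):
    """Raised when a packaged fixture fails its manifest check."""


@dataclass(frozen=True)
class D50Point:
    """An isoeffect observation: total dose (Gy) at 50% RIM incidence in n fractions."""

    d50: float
    n_fractions: int

    def __post_init__(self) -> None:
        if not self.d50 > 0:
            raise ValueError(f"d50 must be > 0 Gy, got {self.d50}")
        if self.n_fractions < 1:
            raise ValueError(f"n_fractions must be >= 1, got {self.n_fractions}")


@dataclass(frozen=True)
class RatDataset:
    """One experiment's isoeffect curve, tagged with cord site and follow-up."""

    study_label: str
    site: str
    follow_up_days: float
    points: tuple
    normalization_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.site not in RAT_SITES:
            raise ValueError(f"unknown cord site {self.site!r}")
        if not self.follow_up_days > 0:
            raise ValueError("follow_up_days must be positive")
        pts = tuple(self.points)
        if len(pts) < 3:
            raise ValueError(
                f"{self.study_label}: need >= 3 points for a 2-parameter fit, got {len(pts)}"
            )
        object.__setattr__(self, "points", pts)

    @property
    def subgroup(self) -> str:
        return CERVICAL_SUBGROUP if self.site == "cervical" else THORACOLUMBAR_SUBGROUP

    def single_fraction_d50(self) -> float:
        sf = [p.d50 for p in self.points if p.n_fractions == 1]
        if len(sf) != 1:
            raise ValueError(
                f"{self.study_label}: expected exactly one single-fraction point, found {len(sf)}"
            )
        return sf[0]

    def scaled(self, factor: float) -> "RatDataset":
        """A copy with every D50 multiplied by ``factor`` (factors compose)."""
        if not factor > 0:
            raise ValueError("scale factor must be positive")
        pts = tuple(D50Point(p.d50 * factor, p.n_fractions) for p in self.points)
        return replace(
            self, points=pts, normalization_factor=self.normalization_factor * factor
        )


@dataclass(frozen=True)
class RIMCohort:
    """A binomial myelopathy outcome attached to a treatment course."""

    study_label: str
    species: str
    site: str
    events: int
    total: int
    course: TreatmentCourse
    included: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.site not in COHORT_SITES:
            raise ValueError(f"unknown cord site {self.site!r}")
        if self.total < 1:
            raise ValueError(f"total must be >= 1, got {self.total}")
        if not 0 <= self.events <= self.total:
            raise ValueError(
                f"{self.study_label}: events must satisfy 0 <= events <= total, "
                f"got {self.events}/{self.total}"
            )

    @property
    def prim(self) -> float:
        """Observed proportion of radiation-induced myelopathy."""
        return self.events / self.total


@dataclass(frozen=True)
class CorrectionLedgerEntry:
    """One documented change to the cohort table, applied on load."""

    point_id: str
    data_field: str
    original_value: str
    corrected_value: str
    action: str  # "modify" | "exclude"
    rationale: str


# ---------------------------------------------------------------------------
# packaged fixtures


def _fixture_bytes(name: str) -> bytes:
    return resources.files("cordtol.data").joinpath(name).read_bytes()


def _verify_fixture(name: str) -> str:
    raw = _fixture_bytes(name)
    manifest = json.loads(_fixture_bytes("manifest.json"))
    entry = manifest.get(name)
    if entry is None:
        raise FixtureIntegrityError(f"{name} missing from fixture manifest")
    digest = hashlib.sha256(raw).hexdigest()
    text = raw.decode("utf-8")
    n_rows = len(text.strip().splitlines()) - 1
    if digest != entry["sha256"] or n_rows != entry["n_rows"]:
        raise FixtureIntegrityError(
            f"{name}: checksum/shape mismatch (expected {entry['n_rows']} rows)"
        )
    return text


def load_rat_table() -> List[RatDataset]:
    """The packaged rat isoeffect table: 6 datasets, 29 (D50, n) points."""
    return read_rat_csv(io.StringIO(_verify_fixture("rat_d50.csv")))


def load_corrections() -> List[CorrectionLedgerEntry]:
    text = _verify_fixture("corrections.csv")
    out = []
    for row in csv.DictReader(io.StringIO(text)):
        out.append(
            CorrectionLedgerEntry(
                point_id=row["point_id"],
                data_field=row["field"],
                original_value=row["original_value"],
                corrected_value=row["corrected_value"],
                action=row["action"],
                rationale=row["rationale"],
            )
        )
    return out


def apply_ledger(
    cohorts: Sequence[RIMCohort], ledger: Sequence[CorrectionLedgerEntry]
) -> List[RIMCohort]:
    """Return ``cohorts`` with every ledger entry applied.

    Entries address cohorts by study label; each must match at least one cohort.
    """
    out = list(cohorts)
    for entry in ledger:
        matched = False
        for i, c in enumerate(out):
            if c.study_label != entry.point_id:
                continue
            if entry.action == "exclude":
                out[i] = replace(c, included=False)
                matched = True
            elif entry.action == "modify":
                if entry.data_field == "course":
                    if format_course(c.course) != entry.original_value:
                        continue
                    out[i] = replace(c, course=parse_course(entry.corrected_value))
                elif entry.data_field == "total":
                    if c.total != int(entry.original_value):
                        continue
                    out[i] = replace(c, total=int(entry.corrected_value))
                elif entry.data_field == "events":
                    if c.events != int(entry.original_value):
                        continue
                    out[i] = replace(c, events=int(entry.corrected_value))
                else:
                    raise ValueError(f"unsupported correction field {entry.data_field!r}")
                matched = True
            else:
                raise ValueError(f"unknown correction action {entry.action!r}")
        if not matched:
            raise ValueError(f"correction {entry.point_id!r} matched no cohort")
    return out


def load_cohort_table(apply_corrections: bool = True) -> List[RIMCohort]:
    """The packaged cohort table (16 large-animal + 25 human cohorts).

    With ``apply_corrections=True`` (default) the corrections ledger is applied: the
    Atkins course becomes 12 Gy × 2, the Eichhorn denominator 46, and the
    Abbatucci cohort is flagged ``included=False``.  With ``apply_corrections=False`` the
    table is returned exactly as originally transcribed.
    """
    cohorts = read_cohort_csv(io.StringIO(_verify_fixture("rim_cohorts.csv")))
    if apply_corrections:
        cohorts = apply_ledger(cohorts, load_corrections())
    return cohorts


def group_cohorts(cohorts: Sequence[RIMCohort], group: str) -> List[RIMCohort]:
    """Select an analysis group: "B" large animals, "C" humans, "D" = B ∪ C.

    Only cohorts with ``included=True`` are returned; excluded cohorts never
    enter a fit unless re-included explicitly.
    """
    group = group.upper()
    if group == "B":
        keep = lambda c: c.species != "human"
    elif group == "C":
        keep = lambda c: c.species == "human"
    elif group == "D":
        keep = lambda c: True
    else:
        raise ValueError(f"unknown group {group!r} (expected B, C or D)")
    return [c for c in cohorts if c.included and keep(c)]


# ---------------------------------------------------------------------------
# CSV schemas
#
# rat:    study,site,follow_up_days,d50_gy,n_fractions   (one row per point)
# cohort: study,species,site,events,total,course,included,note

_RAT_COLUMNS = ["study", "site", "follow_up_days", "d50_gy", "n_fractions"]
_COHORT_COLUMNS = ["study", "species", "site", "events", "total", "course", "included", "note"]


def _open(path_or_buf, mode="r"):
    if isinstance(path_or_buf, (str, Path)):
        return open(path_or_buf, mode, newline="")
    return path_or_buf


def read_rat_csv(path_or_buf) -> List[RatDataset]:
    """Read rat isoeffect data; groups rows into datasets by study label."""
    fh = _open(path_or_buf)
    reader = csv.DictReader(fh)
    missing = set(_RAT_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise ValueError(f"rat CSV missing columns: {sorted(missing)}")
    order: List[str] = []
    rows: dict = {}
    for lineno, row in enumerate(reader, start=2):
        try:
            label = row["study"]
            meta = (row["site"], float(row["follow_up_days"]))
            point = D50Point(float(row["d50_gy"]), int(row["n_fractions"]))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"rat CSV row {lineno}: {exc}") from exc
        if label not in rows:
            rows[label] = (meta, [])
            order.append(label)
        elif rows[label][0] != meta:
            raise ValueError(f"rat CSV row {lineno}: inconsistent metadata for {label!r}")
        rows[label][1].append(point)
    return [
        RatDataset(label, rows[label][0][0], rows[label][0][1], tuple(rows[label][1]))
        for label in order
    ]


def write_rat_csv(datasets: Iterable[RatDataset], path_or_buf) -> None:
    fh = _open(path_or_buf, "w")
    writer = csv.writer(fh)
    writer.writerow(_RAT_COLUMNS)
    for ds in datasets:
        for p in ds.points:
            writer.writerow(
                [ds.study_label, ds.site, f"{ds.follow_up_days:g}", f"{p.d50:g}", p.n_fractions]
            )
    if hasattr(fh, "flush"):
        fh.flush()


def read_cohort_csv(path_or_buf) -> List[RIMCohort]:
    fh = _open(path_or_buf)
    reader = csv.DictReader(fh)
    missing = set(_COHORT_COLUMNS) - set(reader.fieldnames or [])
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    out = []
    for lineno, row in enumerate(reader, start=2):
        try:
            out.append(
                RIMCohort(
                    study_label=row["study"],
                    species=row["species"],
                    site=row["site"],
                    events=int(row["events"]),
                    total=int(row["total"]),
                    course=parse_course(row["course"]),
                    included=row["included"].strip().lower() in ("true", "1", "yes"),
                    note=row.get("note") or "",
                )
            )
        except ValueError as exc:
            raise ValueError(f"cohort CSV row {lineno}: {exc}") from exc
    return out


def write_cohort_csv(cohorts: Iterable[RIMCohort], path_or_buf) -> None:
    fh = _open(path_or_buf, "w")
    writer = csv.writer(fh)
    writer.writerow(_COHORT_COLUMNS)
    for c in cohorts:
        writer.writerow(
            [
                c.study_label,
                c.species,
                c.site,
                c.events,
                c.total,
                format_course(c.course),
                str(c.included),
                c.note,
            ]
        )
    if hasattr(fh, "flush"):
        fh.flush()
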
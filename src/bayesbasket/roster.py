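"""Patient rosters, cohort formation, and descriptive program summaries.

A roster is the patient-level record of a molecularly driven basket program:
one row per treated patient carrying the agent arm, tumor type, qualifying
alterations, enrolling site, timing, and the 16-week clinical-benefit
outcome. This module owns the on-disk CSV dialect, the cohort-formation
rule (a tumor-type cohort exists within an arm once >= 4 such patients are
enrolled), and the descriptive tabulations (clinical-benefit rates,
alteration frequencies, arm/site summaries).

Two denominators are carried throughout and never conflated: *treated*
patients (all dosed rows in the roster) and *evaluable* patients (those
with a 16-week assessment). Percentages use half-up rounding to one
decimal, the convention of the program's printed tables.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Agent registry: the eight single-agent arms, in protocol order.
ARMS: tuple[str, ...] = (
    "buparlisib",
    "dovitinib",
    "binimetinib",
    "encorafenib",
    "sonidegib",
    "bgj398",
    "ceritinib",
    "ribociclib",
)

SITE_TYPES: tuple[str, ...] = ("research_network", "community", "academic")

ROSTER_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "arm",
    "tumor_type",
    "alterations",
    "site_id",
    "site_type",
    "enroll_week",
    "startup_weeks",
    "evaluable_16wk",
    "clinical_benefit_16wk",
    "prior_lines",
)

_TRUE_TOKENS = {"true", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "0", "no", "n"}
_MISSING_TOKENS = {"", "na", "nan", "none", "missing"}


class RosterSchemaError(ValueError):
    """A roster file is missing a required column."""


class RosterParseError(ValueError):
    """A roster row holds an unparseable token."""


class UndefinedRateError(ZeroDivisionError):
    """A rate was requested with a zero denominator."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as printed tables do.

    ``round_half_up(13.75, 1) == 13.8`` regardless of binary float
    representation; needed because 11/80 must render as 13.8%.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PatientRecord:
    """One treated patient.

    ``clinical_benefit_16wk`` is None exactly when the patient is not
    evaluable at 16 weeks; enrollment is molecularly driven so
    ``alterations`` is never empty.
    """

    patient_id: str
    arm: str
    tumor_type: str
    alterations: list[str]
    site_id: str
    site_type: str
    enroll_week: float
    startup_weeks: float
    evaluable_16wk: bool
    clinical_benefit_16wk: bool | None
    prior_lines: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; registry: {ARMS}")
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if not self.alterations:
            raise ValueError(
                f"patient {self.patient_id}: alterations must be non-empty "
                "(enrollment is molecularly driven)"
            )
        if not self.evaluable_16wk and self.clinical_benefit_16wk is not None:
            raise ValueError(
                f"patient {self.patient_id}: outcome present but not evaluable"
            )
        if self.evaluable_16wk and self.clinical_benefit_16wk is None:
            raise ValueError(
                f"patient {self.patient_id}: evaluable but outcome missing"
            )
        if self.enroll_week < 0:
            raise ValueError("enroll_week must be non-negative")
        if self.startup_weeks <= 0:
            raise ValueError("startup_weeks must be positive")


@dataclass
class CohortData:
    """Per-(arm, tumor type) endpoint summary with its historical rate p0."""

    arm: str
    tumor_type: str
    n_evaluable: int
    n_benefit: int
    p0: float | None = None
    n_enrolled: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_benefit <= self.n_evaluable:
            raise ValueError("need 0 <= n_benefit <= n_evaluable")
        if self.p0 is not None and not 0.0 < self.p0 < 1.0:
            raise ValueError("historical rate p0 must lie strictly in (0,1)")

    @property
    def label(self) -> str:
        return f"{self.arm}:{self.tumor_type}"


@dataclass(frozen=True)
class RateSummary:
    """A numerator/denominator pair with its printed one-decimal percent."""

    numerator: int
    denominator: int
    percent: float = field(init=False)

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise UndefinedRateError("rate undefined for zero denominator")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must lie in [0, denominator]")
        object.__setattr__(
            self,
            "percent",
            round_half_up(100.0 * self.numerator / self.denominator, 1),
        )


def clinical_benefit_rate(n_benefit: int, n_dosed: int) -> RateSummary:
    """Clinical benefit rate: CR, PR or SD at 16 weeks, over dosed patients."""
    return RateSummary(n_benefit, n_dosed)


def _parse_bool(token: str, row: int, column: str) -> bool | None:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    if low in _MISSING_TOKENS:
        return None
    raise RosterParseError(
        f"row {row}: cannot parse {column}={token!r} as boolean"
    )


def read_roster(path: str | Path, known_tumor_types: Iterable[str] | None = None) -> list[PatientRecord]:
    """Read a roster CSV into :class:`PatientRecord` objects.

    Missing 16-week outcomes parse as missing (not-evaluable), never as
    False. Unknown tumor-type labels pass through with a logged warning
    when a vocabulary is supplied.
    """
    path = Path(path)
    vocab = set(known_tumor_types) if known_tumor_types is not None else None
    records: list[PatientRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ROSTER_COLUMNS if c not in header]
        if missing:
            raise RosterSchemaError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        for i, row in enumerate(reader, start=2):
            evaluable = _parse_bool(row["evaluable_16wk"], i, "evaluable_16wk")
            if evaluable is None:
                evaluable = False
            benefit = _parse_bool(
                row["clinical_benefit_16wk"], i, "clinical_benefit_16wk"
            )
            if not evaluable:
                benefit = None
            tumor = row["tumor_type"].strip()
            if vocab is not None and tumor not in vocab:
                logger.warning("row %d: unknown tumor type %r", i, tumor)
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    arm=row["arm"].strip().lower(),
                    tumor_type=tumor,
                    alterations=[a for a in row["alterations"].split(";") if a],
                    site_id=row["site_id"],
                    site_type=row["site_type"].strip(),
                    enroll_week=float(row["enroll_week"]),
                    startup_weeks=float(row["startup_weeks"]),
                    evaluable_16wk=evaluable,
                    clinical_benefit_16wk=benefit,
                    prior_lines=int(row["prior_lines"]),
                )
            )
    return records


def write_roster(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records as the roster CSV dialect read by :func:`read_roster`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.arm,
                    r.tumor_type,
                    ";".join(r.alterations),
                    r.site_id,
                    r.site_type,
                    f"{r.enroll_week:g}",
                    f"{r.startup_weeks:g}",
                    str(r.evaluable_16wk).lower(),
                    "" if r.clinical_benefit_16wk is None
                    else str(r.clinical_benefit_16wk).lower(),
                    r.prior_lines,
                ]
            )


def form_cohorts(
    records: Sequence[PatientRecord], min_size: int = 4
) -> list[CohortData]:
    """Form tumor-type cohorts within each arm.

    A cohort for a tumor type exists once at least ``min_size`` patients of
    that type are enrolled in the arm. Historical rates are attached later
    (see :func:`attach_historical_rates`); returned cohorts have ``p0=None``.
    """
    counts: dict[tuple[str, str], list[PatientRecord]] = {}
    for r in records:
        counts.setdefault((r.arm, r.tumor_type), []).append(r)
    cohorts = []
    for (arm, tumor), members in sorted(counts.items()):
        if len(members) < min_size:
            continue
        evaluable = [m for m in members if m.evaluable_16wk]
        cohorts.append(
            CohortData(
                arm=arm,
                tumor_type=tumor,
                n_evaluable=len(evaluable),
                n_benefit=sum(bool(m.clinical_benefit_16wk) for m in evaluable),
                p0=None,
                n_enrolled=len(members),
            )
        )
    return cohorts


def attach_historical_rates(
    cohorts: Sequence[CohortData], rates: pd.DataFrame | str | Path
) -> list[CohortData]:
    """Attach p0 from a historical-rates table (columns arm, tumor_type, p0)."""
    if not isinstance(rates, pd.DataFrame):
        rates = pd.read_csv(rates)
    lookup = {
        (row.arm, row.tumor_type): float(row.p0) for row in rates.itertuples()
    }
    out = []
    for c in cohorts:
        key = (c.arm, c.tumor_type)
        if key not in lookup:
            raise RosterSchemaError(f"no historical rate p0 for cohort {c.label}")
        out.append(
            CohortData(c.arm, c.tumor_type, c.n_evaluable, c.n_benefit,
                       lookup[key], c.n_enrolled)
        )
    return out


def alteration_frequency(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Count patients per alteration label.

    The percent denominator is the number of treated patients; a patient
    with several labels counts once per label, so percents may sum past 100.
    """
    n = len(records)
    counts: dict[str, int] = {}
    for r in records:
        for label in set(r.alterations):
            counts[label] = counts.get(label, 0) + 1
    rows = [
        {"alteration": a, "count": c,
         "percent": round_half_up(100.0 * c / n, 1) if n else 0.0}
        for a, c in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["alteration", "count", "percent"])
    return df.sort_values(["count", "alteration"], ascending=[False, True],
                          ignore_index=True)


def summarize_program(
    records: Sequence[PatientRecord], sites: pd.DataFrame | None = None
) -> dict:
    """Arm-level and site-type-level tabulations of a roster.

    Returns a dict with:

    ``arms``
        DataFrame per arm: treated, dosed-evaluable, benefit count, CBR %.
    ``site_types``
        DataFrame per site type: treated count and start-up mean/median/range
        (openings count when a site-registry table is supplied).
    ``totals``
        treated, evaluable, benefit, pooled CBR, and openings when known.
    """
    arm_rows = []
    for arm in ARMS:
        sub = [r for r in records if r.arm == arm]
        ev = [r for r in sub if r.evaluable_16wk]
        nb = sum(bool(r.clinical_benefit_16wk) for r in ev)
        arm_rows.append(
            {
                "arm": arm,
                "treated": len(sub),
                "evaluable": len(ev),
                "benefit": nb,
                "cbr_percent": (
                    clinical_benefit_rate(nb, len(ev)).percent if ev else None
                ),
            }
        )
    arms = pd.DataFrame(arm_rows)

    site_rows = []
    for st in SITE_TYPES:
        sub = [r for r in records if r.site_type == st]
        if sites is not None:
            open_sub = sites[sites["site_type"] == st]
            startup = open_sub["startup_weeks"]
            n_open = len(open_sub)
        else:
            # fall back to per-patient startup times (openings unknown)
            startup = pd.Series([r.startup_weeks for r in sub], dtype=float)
            n_open = None
        site_rows.append(
            {
                "site_type": st,
                "treated": len(sub),
                "openings": n_open,
                "startup_mean": float(startup.mean()) if len(startup) else None,
                "startup_median": float(startup.median()) if len(startup) else None,
                "startup_min": float(startup.min()) if len(startup) else None,
                "startup_max": float(startup.max()) if len(startup) else None,
            }
        )
    site_types = pd.DataFrame(site_rows)

    evaluable = [r for r in records if r.evaluable_16wk]
    n_benefit = sum(bool(r.clinical_benefit_16wk) for r in evaluable)
    totals = {
        "treated": len(records),
        "evaluable": len(evaluable),
        "benefit": n_benefit,
        "cbr_percent": (
            clinical_benefit_rate(n_benefit, len(evaluable)).percent
            if evaluable
            else None
        ),
        "openings": int(len(sites)) if sites is not None else None,
        "unique_sites": (
            int(sites["site_id"].nunique()) if sites is not None else None
        ),
    }
    return {"arms": arms, "site_types": site_types, "totals": totals}
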
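"""Synthetic patient rosters matching a completed basket program's marginals.

The program this package models never deposited patient-level data, so
every downstream module is exercised against synthetic rosters generated
here. In ``exact`` mode the generator deterministically allocates patients
so that every published marginal is hit exactly — per-arm treated counts,
per-arm 16-week clinical-benefit counts over their dosed denominators,
site-type treated totals and protocol-opening counts, tumor-type counts,
and alteration counts — while the *joint* structure (which alterations
co-occur with which tumor types at which sites) is filled by a seeded
round-robin and is NOT an estimate of the real joint distribution: the
generator guarantees marginals only. ``sampled`` mode draws rosters of any
size from multinomials with the spec's proportions.

One table-reconciliation detail is built in: one arm reports 84 treated
patients but only 82 dosed/evaluable for the primary endpoint, so exactly
two of its patients are emitted with ``evaluable_16wk=False``, making the
treated denominator 595 and the evaluable denominator 593 simultaneously
correct. The RAS alteration count is a union label: its KRAS/NRAS/HRAS
sub-labels sum past the union because some patients carry more than one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .roster import ARMS, SITE_TYPES, PatientRecord

TUMOR_TYPE_COUNTS: dict[str, int] = {
    "colorectal": 55,
    "nsclc_adeno": 54,
    "ovarian": 50,
    "sarcoma": 45,
    "hnscc": 32,
    "uterine": 20,
    "gallbladder_biliary": 17,
    "anal": 10,
    "mesothelioma": 6,
    "vaginal": 5,
    "thymus": 4,
    "germ_cell": 3,
    "penile": 2,
}

#: Tumor-type cohorts (>= 4 patients) observed per arm; the exact-mode
#: generator seeds 4 patients for each so cohort formation reproduces them.
ARM_COHORT_TYPES: dict[str, tuple[str, ...]] = {
    "buparlisib": (
        "colorectal", "sarcoma", "ovarian", "cervical", "hnscc", "anal",
        "gallbladder_biliary", "bladder", "ge_junction", "liver",
        "skin_nonmelanoma", "small_intestine", "thyroid", "unknown_primary",
        "vaginal", "neuroendocrine",
    ),
    "dovitinib": (
        "gist", "colorectal", "ovarian", "adenoid_cystic", "hnscc",
        "nsclc_adeno", "thymus",
    ),
    "binimetinib": (
        "nsclc_adeno", "ovarian", "uterine", "appendix", "small_intestine",
        "sarcoma", "thyroid", "unknown_primary", "breast", "bladder",
        "ge_junction", "neuroendocrine",
    ),
    "encorafenib": ("thyroid",),
    "sonidegib": (),
    "bgj398": ("breast", "colorectal", "hnscc", "nsclc_adeno", "ovarian"),
    "ceritinib": ("colorectal", "nsclc_adeno", "sarcoma"),
    "ribociclib": (
        "nsclc_adeno", "hnscc", "sarcoma", "uterine", "nsclc_squamous",
        "breast_triple_negative", "mesothelioma", "pancreatic", "bladder",
        "ge_junction", "unknown_primary", "head_neck_nonsquamous",
    ),
}


class FeasibilityError(ValueError):
    """A program spec's constraints cannot be satisfied simultaneously."""


@dataclass
class ProgramSpec:
    """Published program marginals driving the generator."""

    arm_sizes: dict[str, int]
    benefit_counts: dict[str, int]
    dosed_counts: dict[str, int]
    site_type_treated: dict[str, int]
    site_type_openings: dict[str, int]
    site_type_unique_sites: dict[str, int]
    startup_median_weeks: dict[str, float]
    startup_mean_weeks: dict[str, float]
    tumor_type_counts: dict[str, int] = field(
        default_factory=lambda: dict(TUMOR_TYPE_COUNTS)
    )
    alteration_counts: dict[str, int] = field(
        default_factory=lambda: {"PIK3CA": 93, "RAS": 80, "CDKN2A": 78, "PTEN": 60}
    )
    ras_sublabels: dict[str, int] = field(
        default_factory=lambda: {"KRAS": 67, "NRAS": 14, "HRAS": 3}
    )
    funnel: tuple[int, int, int, int] = (1674, 1568, 988, 595)
    drop_reasons: dict[str, int] = field(
        default_factory=lambda: {
            "unacceptable_laboratory_values": 116,
            "unacceptable_test_procedure_results": 57,
            "other": 99,
        }
    )
    drop_reason_denominator: int = 414
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.arm_sizes.values())
        if total != self.funnel[-1]:
            raise FeasibilityError(
                f"arm sizes sum to {total}, funnel treated stage is {self.funnel[-1]}"
            )
        for arm, nb in self.benefit_counts.items():
            if nb > self.dosed_counts[arm]:
                raise FeasibilityError(
                    f"arm {arm}: benefit count {nb} exceeds dosed {self.dosed_counts[arm]}"
                )
            if self.dosed_counts[arm] > self.arm_sizes[arm]:
                raise FeasibilityError(
                    f"arm {arm}: dosed {self.dosed_counts[arm]} exceeds treated"
                )
        if sum(self.site_type_treated.values()) != total:
            raise FeasibilityError("site-type treated counts must sum to program total")
        if sum(self.tumor_type_counts.values()) > total:
            raise FeasibilityError("tumor-type counts exceed program total")
        for st, s in self.site_type_unique_sites.items():
            if s > self.site_type_openings[st]:
                raise FeasibilityError(f"{st}: more unique sites than openings")

    @property
    def total_treated(self) -> int:
        return sum(self.arm_sizes.values())

    @property
    def n_other_tumor(self) -> int:
        return self.total_treated - sum(self.tumor_type_counts.values())


def default_program_spec() -> ProgramSpec:
    """The program's printed counts: eight arms, 595 treated patients."""
    return ProgramSpec(
        arm_sizes=dict(zip(ARMS, (146, 80, 110, 12, 10, 84, 47, 106))),
        benefit_counts=dict(zip(ARMS, (22, 11, 25, 3, 0, 12, 9, 19))),
        dosed_counts=dict(zip(ARMS, (146, 80, 110, 12, 10, 82, 47, 106))),
        site_type_treated=dict(zip(SITE_TYPES, (166, 196, 233))),
        site_type_openings=dict(zip(SITE_TYPES, (118, 197, 81))),
        site_type_unique_sites=dict(zip(SITE_TYPES, (57, 96, 39))),
        startup_median_weeks=dict(zip(SITE_TYPES, (2.6, 3.6, 8.1))),
        startup_mean_weeks=dict(zip(SITE_TYPES, (3.6, 5.4, 10.7))),
    )


# ---------------------------------------------------------------------------
# exact-mode allocation helpers
# ---------------------------------------------------------------------------

def _largest_remainder(ideal: np.ndarray, total: int, minima: np.ndarray) -> np.ndarray:
    """Integer apportionment of `total` proportional to `ideal`, >= minima."""
    ideal = np.maximum(ideal, minima)
    scaled = ideal * (total / ideal.sum()) if ideal.sum() else ideal
    out = np.maximum(np.floor(scaled).astype(int), minima)
    rem = total - out.sum()
    order = np.argsort(-(scaled - np.floor(scaled)))
    i = 0
    while rem != 0:
        j = order[i % len(order)]
        if rem > 0:
            out[j] += 1
            rem -= 1
        elif out[j] > minima[j]:
            out[j] -= 1
            rem += 1
        i += 1
    return out


def _interleaved_labels(counts: Mapping[str, int]) -> list[str]:
    """Merge label blocks so each label spreads evenly through the sequence."""
    keyed = []
    for label, count in counts.items():
        for j in range(count):
            keyed.append(((j + 0.5) / count, label))
    return [label for _, label in sorted(keyed, key=lambda t: (t[0], t[1]))]


def _allocate_tumor_types(spec: ProgramSpec) -> dict[str, list[str]]:
    """Per-arm tumor-type lists: seed 4 per observed cohort, fill remainder."""
    remaining = dict(spec.tumor_type_counts)
    other_budget = spec.n_other_tumor
    per_arm: dict[str, list[str]] = {a: [] for a in spec.arm_sizes}
    for arm, types in ARM_COHORT_TYPES.items():
        if arm not in spec.arm_sizes:
            continue
        for t in types:
            if t in remaining:
                if remaining[t] < 4:
                    raise FeasibilityError(
                        f"tumor type {t}: count too small to seed cohort for {arm}"
                    )
                remaining[t] -= 4
            else:
                if other_budget < 4:
                    raise FeasibilityError("'other' tumor budget exhausted")
                other_budget -= 4
            per_arm[arm].extend([t] * 4)
        if len(per_arm[arm]) > spec.arm_sizes[arm]:
            raise FeasibilityError(f"arm {arm}: cohort seeds exceed arm size")
    # round-robin fill of the remaining slots from the remaining inventory
    pool = _interleaved_labels({**remaining, "other": other_budget})
    idx = 0
    for arm in spec.arm_sizes:
        while len(per_arm[arm]) < spec.arm_sizes[arm]:
            per_arm[arm].append(pool[idx])
            idx += 1
    assert idx == len(pool)
    return per_arm


def _arm_alterations(arm: str, n: int) -> list[list[str]]:
    """Deterministic per-arm alteration lists hitting the program counts."""
    out: list[list[str]] = []
    if arm == "buparlisib":
        out = [["PIK3CA"]] * 93 + [["PTEN"]] * 53
    elif arm == "dovitinib":
        cycle = (["FGFR1"], ["FGFR3"], ["KIT"], ["FLT3"])
        out = [list(cycle[i % 4]) for i in range(n)]
    elif arm == "binimetinib":
        for i in range(80):
            labels = ["RAS"]
            if i <= 66:
                labels.append("KRAS")
            if i >= 67 or i == 0:
                labels.append("NRAS")
            if 1 <= i <= 3:
                labels.append("HRAS")
            out.append(labels)
        rest = (["NF1"], ["MEK1"])
        out += [list(rest[i % 2]) for i in range(n - 80)]
        for i in range(80, 87):  # 7 extra PTEN co-alterations -> total 60
            out[i].append("PTEN")
    elif arm == "encorafenib":
        out = [["BRAF_V600E"]] * n
    elif arm == "sonidegib":
        out = [["PTCH1"]] * 8 + [["SMO"]] * (n - 8)
    elif arm == "bgj398":
        cycle = (["FGFR1_amp"], ["FGFR2"], ["FGFR3"], ["FGF_ligand_amp"])
        out = [list(cycle[i % 4]) for i in range(n)]
    elif arm == "ceritinib":
        out = [["ALK"]] * 30 + [["ROS1"]] * (n - 30)
    elif arm == "ribociclib":
        out = [["CDKN2A"]] * 78
        cycle = (["CCND1_amp"], ["CDK4_amp"], ["CDK6_amp"])
        out += [list(cycle[i % 3]) for i in range(n - 78)]
    else:
        out = [["OTHER"]] * n
    if len(out) != n:
        raise FeasibilityError(f"arm {arm}: alteration plan sized for != {n}")
    return out


def generate_sites(spec: ProgramSpec, seed: int | None = None) -> pd.DataFrame:
    """Site registry: one row per protocol opening (site x arm).

    Openings per site type and the number of unique sites match the spec
    exactly; start-up times are log-normal draws calibrated to each site
    type's printed median and mean (sigma = sqrt(2 ln(mean/median))).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    arm_order = [a for a in spec.arm_sizes]
    rows = []
    for st in spec.site_type_openings:
        n_open = spec.site_type_openings[st]
        n_sites = spec.site_type_unique_sites[st]
        shares = np.array([spec.arm_sizes[a] for a in arm_order], dtype=float)
        per_arm = _largest_remainder(
            shares, n_open, np.ones(len(arm_order), dtype=int)
        )
        median = spec.startup_median_weeks[st]
        sigma = math.sqrt(
            2.0 * math.log(spec.startup_mean_weeks[st] / median)
        )
        offset = 0
        for arm, count in zip(arm_order, per_arm):
            for k in range(count):
                site_idx = (offset + k) % n_sites
                rows.append(
                    {
                        "site_id": f"{st[:4]}_{site_idx:03d}",
                        "site_type": st,
                        "arm": arm,
                        "startup_weeks": float(
                            math.exp(math.log(median) + sigma * rng.standard_normal())
                        ),
                    }
                )
            offset += count
    df = pd.DataFrame(rows)
    assert df.groupby("site_type").size().to_dict() == dict(spec.site_type_openings)
    assert df["site_id"].nunique() == sum(spec.site_type_unique_sites.values())
    return df


def generate_roster(
    spec: ProgramSpec | None = None,
    mode: str = "exact",
    seed: int | None = None,
    n_patients: int | None = None,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a patient roster (and the site registry it references).

    exact mode: deterministic given the seed; every spec marginal is hit
    exactly. sampled mode: ``n_patients`` independent draws from the spec's
    proportions (marginals converge, nothing is exact).
    """
    spec = spec or default_program_spec()
    seed = spec.seed if seed is None else seed
    if mode == "exact":
        return _generate_exact(spec, seed)
    if mode == "sampled":
        if n_patients is None:
            n_patients = spec.total_treated
        return _generate_sampled(spec, seed, n_patients)
    raise ValueError(f"unknown mode {mode!r}")


def _generate_exact(spec: ProgramSpec, seed: int) -> tuple[list[PatientRecord], pd.DataFrame]:
    rng = np.random.default_rng(seed)
    sites = generate_sites(spec, seed=seed)
    tumor_by_arm = _allocate_tumor_types(spec)
    site_labels = _interleaved_labels(spec.site_type_treated)

    # per-(arm, site_type) patient counts follow from zipping the interleaved
    # site-type stream against arm blocks; openings then serve those cells
    openings_by_cell: dict[tuple[str, str], list[pd.Series]] = {}
    for _, row in sites.iterrows():
        openings_by_cell.setdefault((row["arm"], row["site_type"]), []).append(row)
    cell_cursor: dict[tuple[str, str], int] = {}

    records: list[PatientRecord] = []
    pos = 0
    for arm in spec.arm_sizes:
        n = spec.arm_sizes[arm]
        alterations = _arm_alterations(arm, n)
        tumors = tumor_by_arm[arm]
        n_not_evaluable = spec.arm_sizes[arm] - spec.dosed_counts[arm]
        n_benefit = spec.benefit_counts[arm]
        for i in range(n):
            st = site_labels[pos]
            cell = (arm, st)
            pool = openings_by_cell.get(cell)
            if not pool:  # no opening of this arm at this site type: borrow
                pool = openings_by_cell[
                    next(k for k in openings_by_cell if k[0] == arm)
                ]
            cur = cell_cursor.get(cell, 0)
            opening = pool[cur % len(pool)]
            cell_cursor[cell] = cur + 1
            evaluable = i >= n_not_evaluable  # first rows carry the 84-vs-82 gap
            benefit: bool | None
            if not evaluable:
                benefit = None
            else:
                benefit = (i - n_not_evaluable) < n_benefit
            startup = float(opening["startup_weeks"])
            records.append(
                PatientRecord(
                    patient_id=f"pt_{pos:04d}",
                    arm=arm,
                    tumor_type=tumors[i],
                    alterations=alterations[i],
                    site_id=str(opening["site_id"]),
                    site_type=st,
                    enroll_week=round(startup + 1.5 * (i % 97), 2),
                    startup_weeks=startup,
                    evaluable_16wk=evaluable,
                    clinical_benefit_16wk=benefit,
                    prior_lines=int(min(rng.poisson(3.0), 19)),
                )
            )
            pos += 1
    return records, sites


def _generate_sampled(
    spec: ProgramSpec, seed: int, n_patients: int
) -> tuple[list[PatientRecord], pd.DataFrame]:
    rng = np.random.default_rng(seed)
    sites = generate_sites(spec, seed=seed)
    total = spec.total_treated
    arms = list(spec.arm_sizes)
    arm_p = np.array([spec.arm_sizes[a] for a in arms], dtype=float) / total
    tumor_labels = list(spec.tumor_type_counts) + ["other"]
    tumor_p = np.array(
        [spec.tumor_type_counts[t] for t in spec.tumor_type_counts]
        + [spec.n_other_tumor],
        dtype=float,
    ) / total
    st_labels = list(spec.site_type_treated)
    st_p = np.array([spec.site_type_treated[s] for s in st_labels], dtype=float) / total
    openings_by_type: dict[str, pd.DataFrame] = {
        st: sites[sites["site_type"] == st].reset_index(drop=True)
        for st in st_labels
    }
    records = []
    for i in range(n_patients):
        arm = arms[rng.choice(len(arms), p=arm_p)]
        st = st_labels[rng.choice(len(st_labels), p=st_p)]
        pool = openings_by_type[st]
        opening = pool.iloc[int(rng.integers(len(pool)))]
        evaluable = bool(rng.uniform() >= (total - sum(spec.dosed_counts.values())) / total)
        dosed = spec.dosed_counts[arm]
        benefit = (
            bool(rng.uniform() < spec.benefit_counts[arm] / dosed)
            if evaluable and dosed
            else (False if evaluable else None)
        )
        startup = float(opening["startup_weeks"])
        records.append(
            PatientRecord(
                patient_id=f"spt_{i:04d}",
                arm=arm,
                tumor_type=tumor_labels[rng.choice(len(tumor_labels), p=tumor_p)],
                alterations=_arm_alterations(arm, spec.arm_sizes[arm])[
                    int(rng.integers(spec.arm_sizes[arm]))
                ],
                site_id=str(opening["site_id"]),
                site_type=st,
                enroll_week=float(rng.uniform(0, 150)),
                startup_weeks=startup,
                evaluable_16wk=evaluable,
                clinical_benefit_16wk=benefit,
                prior_lines=int(min(rng.poisson(3.0), 19)),
            )
        )
    return records, sites


def generate_funnel(
    spec: ProgramSpec | None = None,
    mode: str = "exact",
    seed: int | None = None,
    stage_probs: tuple[float, float, float] | None = None,
) -> dict:
    """Prescreening funnel: checklists -> actionable -> consented -> treated.

    exact mode returns the printed stage counts and itemized drop reasons;
    sampled mode draws stagewise binomials (retention probabilities default
    to the printed stage ratios, overridable via ``stage_probs``).
    """
    spec = spec or default_program_spec()
    if mode == "exact":
        return {
            "stages": tuple(spec.funnel),
            "drop_reasons": dict(spec.drop_reasons),
            "drop_reason_denominator": spec.drop_reason_denominator,
            "unclassified": spec.drop_reason_denominator
            - sum(spec.drop_reasons.values()),
        }
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if stage_probs is None:
        stage_probs = tuple(
            spec.funnel[i + 1] / spec.funnel[i] for i in range(3)
        )
    stages = [spec.funnel[0]]
    for p in stage_probs:
        stages.append(int(rng.binomial(stages[-1], p)))
    return {"stages": tuple(stages), "drop_reasons": None,
            "drop_reason_denominator": None, "unclassified": None}
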
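import io

import numpy as np
import pytest
from scipy.stats import chisquare

from bayesbasket.roster import (
    alteration_frequency,
    clinical_benefit_rate,
    form_cohorts,
    summarize_program,
    write_roster,
)
from bayesbasket.synthetic import (
    ARM_COHORT_TYPES,
    FeasibilityError,
    ProgramSpec,
    default_program_spec,
    generate_funnel,
    generate_roster,
    generate_sites,
)


class TestDefaultSpec:
    def test_marginal_sums(self, program_spec):
        assert sum(program_spec.arm_sizes.values()) == 595
        assert sum(program_spec.benefit_counts.values()) == 101
        assert sum(program_spec.dosed_counts.values()) == 593
        assert sum(program_spec.site_type_treated.values()) == 595
        assert sum(program_spec.site_type_openings.values()) == 396
        assert sum(program_spec.site_type_unique_sites.values()) == 192

    def test_infeasible_spec_names_constraint(self, program_spec):
        bad = {**program_spec.benefit_counts, "sonidegib": 11}
        with pytest.raises(FeasibilityError, match="sonidegib"):
            ProgramSpec(
                arm_sizes=program_spec.arm_sizes,
                benefit_counts=bad,
                dosed_counts=program_spec.dosed_counts,
                site_type_treated=program_spec.site_type_treated,
                site_type_openings=program_spec.site_type_openings,
                site_type_unique_sites=program_spec.site_type_unique_sites,
                startup_median_weeks=program_spec.startup_median_weeks,
                startup_mean_weeks=program_spec.startup_mean_weeks,
            )


class TestExactMode:
    def test_every_spec_marginal_matches(self, program_spec, exact_roster):
        records, sites = exact_roster
        by_arm = {arm: [r for r in records if r.arm == arm]
                  for arm in program_spec.arm_sizes}
        # arm sizes (treated), dosed (evaluable), benefit counts
        for arm, size in program_spec.arm_sizes.items():
            assert len(by_arm[arm]) == size, arm
            evaluable = [r for r in by_arm[arm] if r.evaluable_16wk]
            assert len(evaluable) == program_spec.dosed_counts[arm], arm
            assert (
                sum(bool(r.clinical_benefit_16wk) for r in evaluable)
                == program_spec.benefit_counts[arm]
            ), arm
        # site-type treated counts, openings, unique sites
        for st, n in program_spec.site_type_treated.items():
            assert sum(r.site_type == st for r in records) == n, st
        assert sites.groupby("site_type").size().to_dict() == (
            program_spec.site_type_openings
        )
        assert sites["site_id"].nunique() == 192
        # tumor-type counts
        for tumor, n in program_spec.tumor_type_counts.items():
            assert sum(r.tumor_type == tumor for r in records) == n, tumor
        # alteration counts, including the RAS union and sub-labels
        freq = alteration_frequency(records).set_index("alteration")["count"]
        for label, n in {**program_spec.alteration_counts,
                         **program_spec.ras_sublabels}.items():
            assert freq[label] == n, label

    def test_pooled_totals_row(self, exact_roster):
        records, _ = exact_roster
        totals = summarize_program(records)["totals"]
        assert (totals["treated"], totals["evaluable"], totals["benefit"]) == (
            595, 593, 101
        )
        assert clinical_benefit_rate(totals["benefit"], totals["evaluable"]).percent == 17.0

    def test_alteration_percents(self, exact_roster):
        records, _ = exact_roster
        freq = alteration_frequency(records).set_index("alteration")["percent"]
        assert freq["PIK3CA"] == 15.6
        assert freq["RAS"] == 13.4
        assert freq["CDKN2A"] == 13.1
        assert freq["PTEN"] == 10.1

    def test_observed_cohorts_are_reproduced(self, exact_roster):
        """Each arm's observed tumor-type cohorts form from the roster."""
        records, _ = exact_roster
        formed = {}
        for c in form_cohorts(records, min_size=4):
            formed.setdefault(c.arm, set()).add(c.tumor_type)
        for arm, types in ARM_COHORT_TYPES.items():
            assert set(types) <= formed.get(arm, set()), arm

    def test_byte_identical_given_seed(self, program_spec):
        outputs = []
        for _ in range(2):
            records, _ = generate_roster(program_spec, mode="exact", seed=5)
            buf = io.StringIO()
            import csv

            w = csv.writer(buf)
            for r in records:
                w.writerow([r.patient_id, r.arm, r.tumor_type,
                            ";".join(r.alterations), r.site_id, r.site_type,
                            r.enroll_week, r.startup_weeks, r.evaluable_16wk,
                            r.clinical_benefit_16wk, r.prior_lines])
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]


class TestSampledMode:
    def test_small_sample_schema(self, program_spec):
        records, _ = generate_roster(program_spec, mode="sampled", seed=3,
                                     n_patients=10)
        assert len(records) == 10
        for r in records:
            assert r.alterations
            assert r.arm in program_spec.arm_sizes

    def test_arm_marginal_converges(self, program_spec):
        records, _ = generate_roster(program_spec, mode="sampled", seed=4,
                                     n_patients=10_000)
        arms = list(program_spec.arm_sizes)
        observed = np.array([sum(r.arm == a for r in records) for a in arms])
        expected = np.array(
            [program_spec.arm_sizes[a] / 595 * 10_000 for a in arms]
        )
        assert chisquare(observed, expected).pvalue > 0.01


class TestFunnel:
    def test_exact_stages_and_reasons(self, program_spec):
        funnel = generate_funnel(program_spec, mode="exact")
        assert funnel["stages"] == (1674, 1568, 988, 595)
        reasons = funnel["drop_reasons"]
        assert (
            reasons["unacceptable_laboratory_values"],
            reasons["unacceptable_test_procedure_results"],
            reasons["other"],
        ) == (116, 57, 99)
        assert all(v <= funnel["drop_reason_denominator"] for v in reasons.values())
        assert funnel["unclassified"] == 414 - 116 - 57 - 99

    def test_sampled_with_certain_retention(self, program_spec):
        funnel = generate_funnel(program_spec, mode="sampled", seed=0,
                                 stage_probs=(1.0, 1.0, 1.0))
        assert funnel["stages"] == (1674, 1674, 1674, 1674)

    def test_sampled_is_monotone(self, program_spec):
        stages = generate_funnel(program_spec, mode="sampled", seed=8)["stages"]
        assert all(a >= b for a, b in zip(stages, stages[1:]))


def test_site_registry_startup_medians(program_spec):
    sites = generate_sites(program_spec, seed=2)
    for st, median in program_spec.startup_median_weeks.items():
        sub = sites.loc[sites["site_type"] == st, "startup_weeks"]
        # log-normal medians land near the calibrated values even at n~100
        assert abs(np.log(sub.median() / median)) < 0.35, st
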
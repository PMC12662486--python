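"""Product-of-coefficients mediation: decomposition, suppression, scanning."""

import numpy as np
import pytest

from mrmediate.mediation import (
    MediationScanConfig,
    apply_suppression,
    decompose,
    indirect_effect,
    mediation_frame,
    mediation_scan,
    total_effect,
)
from mrmediate.mr_core import MREstimate, _estimate, wald_ratio
from mrmediate.synthetic import StudySimSpec, make_table1_fixture, simulate_study

from conftest import make_pairs


def est(beta, se, method="ivw_random"):
    return _estimate(method, beta, se, 10)


class TestIndirectEffect:
    def test_null_mediator_path_se(self):
        ind = indirect_effect(0.5, 0.1, 0.0, 0.2)
        assert ind.point == 0.0
        assert ind.se == pytest.approx(abs(0.5) * 0.2)

    def test_product_of_published_step_ors(self):
        # ln(0.89) * ln(0.79): the two printed step estimates for carnitine
        a, b = np.log(0.89), np.log(0.79)
        ind = indirect_effect(a, 0.04, b, 0.07)
        assert ind.point == pytest.approx(0.0275, abs=5e-5)

    def test_delta_vs_monte_carlo_agree_for_strong_paths(self):
        # both paths > 3 SEs from zero: delta and MC SEs within 10%
        delta = indirect_effect(0.5, 0.1, 0.4, 0.1)
        mc = indirect_effect(0.5, 0.1, 0.4, 0.1, n_mc=200_000, seed=4)
        assert mc.se == pytest.approx(delta.se, rel=0.10)

    def test_invalid_se_rejected(self):
        with pytest.raises(ValueError):
            indirect_effect(0.5, 0.0, 0.4, 0.1)


class TestDecompose:
    def test_zero_indirect_gives_direct_equals_total(self):
        res = decompose(est(0.2, 0.05), est(0.0, 0.01), est(0.3, 0.05),
                        rule="negative_only")
        assert res.direct == res.c.beta
        assert res.proportion_pct == 0.0

    def test_exact_additive_identity(self):
        res = decompose(est(0.16, 0.01), est(0.3, 0.02), est(0.2, 0.03))
        assert res.direct + res.indirect.point == res.c.beta  # bit-exact

    def test_published_proportion_arithmetic(self):
        # total 0.0959 with indirect 0.0128 -> 13.35% (reported 13.34)
        res = decompose(est(0.0959, 0.2), est(0.0128, 1e-6), est(1.0, 1e-6),
                        rule="negative_only")
        assert res.proportion_pct == pytest.approx(13.35, abs=0.05)

    def test_zero_total_is_suppressed_as_undefined(self):
        res = decompose(est(0.0, 0.05), est(0.3, 0.02), est(0.2, 0.03))
        assert res.proportion_pct is None
        assert res.suppression_reason == "undefined_total"


class TestSuppression:
    def test_ci_including_zero_suppressed_under_footnote_rule(self):
        # the published carnitine CI (-0.0214, 0.0470)
        res = decompose(est(0.0959, 0.0002), est(0.0128, 0.01745), est(1.0, 1e-9),
                        rule="footnote")
        assert res.indirect.ci_low == pytest.approx(-0.0214, abs=5e-4)
        assert res.proportion_pct is None
        assert res.suppression_reason == "ci_includes_zero"

    def test_negative_indirect_suppressed_under_both_rules(self):
        for rule in ("footnote", "negative_only"):
            res = decompose(est(0.0959, 0.001), est(-0.0140, 0.01), est(1.0, 1e-9),
                            rule=rule)
            assert res.proportion_pct is None
            assert res.suppression_reason == "negative_direction"

    def test_clear_positive_mediation_reported_under_both_rules(self):
        for rule in ("footnote", "negative_only"):
            res = decompose(est(0.1, 0.001), est(0.02, 0.0025), est(1.0, 1e-9),
                            rule=rule)
            assert res.indirect.ci_low > 0
            assert res.proportion_pct == pytest.approx(20.0, rel=1e-6)
            assert res.suppression_reason == "none"

    def test_reapplying_rule_switches_suppression(self):
        res = decompose(est(0.0959, 0.0002), est(0.0128, 0.01745), est(1.0, 1e-9),
                        rule="footnote")
        assert res.proportion_pct is None
        relaxed = apply_suppression(res, rule="negative_only")
        assert relaxed.proportion_pct == pytest.approx(13.35, abs=0.05)


class TestReferenceTable:
    def test_row_count_is_fifteen(self):
        assert len(make_table1_fixture()) == 15

    def test_carnitine_row_values(self):
        row = make_table1_fixture().set_index("mediator").loc["Carnitine levels"]
        assert row["indirect_beta"] == 0.0128
        assert (row["ci_low"], row["ci_high"]) == (-0.0214, 0.0470)
        assert row["proportion_pct"] == 13.34

    def test_suppressed_rows_are_exactly_the_negative_betas(self):
        table = make_table1_fixture()
        suppressed = set(table.loc[table["suppressed"], "mediator"])
        assert suppressed == {
            "2-Hydroxyoctanoate levels",
            "4-Methylhexanoylglutamine levels",
            "X-13866 levels",
            "X-22834 levels",
        }
        assert (table.loc[table["suppressed"], "indirect_beta"] < 0).all()

    def test_negative_only_rule_reproduces_published_pattern(self):
        """Re-deriving suppression from the betas under the negative-only
        rule gives 11 reported and 4 suppressed proportions, matching the
        published table."""
        table = make_table1_fixture()
        implied_c = 0.0959  # shared total effect implied by reported rows
        reported = 0
        for row in table.itertuples():
            res = decompose(
                est(implied_c, 1e-9),
                est(row.indirect_beta, 1e-9),
                est(1.0, 1e-9),
                rule="negative_only",
            )
            if res.proportion_pct is not None:
                reported += 1
                assert res.proportion_pct == pytest.approx(
                    100 * row.indirect_beta / implied_c
                )
        assert reported == 11

    def test_proportion_ratios_match_indirect_ratios(self):
        """Co-mediators share one total-effect denominator, so proportion
        ratios equal indirect-effect ratios up to table rounding."""
        table = make_table1_fixture().dropna(subset=["proportion_pct"])
        strong = table[table["indirect_beta"].abs() >= 0.01]
        implied_c = strong["indirect_beta"] / (strong["proportion_pct"] / 100)
        assert implied_c.max() - implied_c.min() < 1e-3
        assert implied_c.mean() == pytest.approx(0.0959, abs=5e-4)
        ratio = (0.0128 / 0.0351) / (13.34 / 36.69)
        assert ratio == pytest.approx(1.0, abs=5e-3)


class TestScan:
    def test_total_effect_single_instrument_is_wald(self):
        pairs = make_pairs([0.2], [0.04], [0.1])
        assert total_effect(pairs).beta == wald_ratio(pairs[0]).beta

    def test_step1_gate_excludes_unassociated_mediator(self):
        """A candidate whose step-1 estimate is non-significant never enters
        the table, whatever its step-2 looks like."""
        study = simulate_study(StudySimSpec(n_taxa=1, n_metabolites=3), seed=5)
        results = mediation_scan(
            study.taxa[0], study.metabolites, study.outcome,
            config=MediationScanConfig(), ld=study.ld,
        )
        ids = {r.mediator_id for r in results}
        assert study.true_mediator in ids
        # null mediators have no exposure->mediator path: excluded by the gate
        # except at the alpha-level false-positive rate (checked in bulk below)

    def test_true_mediator_recovered_and_false_inclusions_rare(self):
        """One true mediator among 10 nulls: recovered in >= 90% of
        replicates, null mediators included at below the alpha level."""
        reps = 60
        spec = StudySimSpec(n_taxa=1, n_metabolites=11)
        hits, false_inclusions, null_trials = 0, 0, 0
        for seed in range(reps):
            study = simulate_study(spec, seed=seed)
            results = mediation_scan(
                study.taxa[0], study.metabolites, study.outcome,
                config=MediationScanConfig(), ld=study.ld,
            )
            ids = {r.mediator_id for r in results}
            hits += study.true_mediator in ids
            false_inclusions += len(ids - {study.true_mediator})
            null_trials += len(study.metabolites) - 1
        assert hits / reps >= 0.90
        assert false_inclusions / null_trials <= 0.05

    def test_alpha_gate_respected(self):
        study = simulate_study(StudySimSpec(n_taxa=1, n_metabolites=2), seed=9)
        strict = MediationScanConfig(alpha=1e-300)
        assert (
            mediation_scan(study.taxa[0], study.metabolites, study.outcome,
                           config=strict, ld=study.ld)
            == []
        )

    def test_report_frame_marks_suppressed_rows(self):
        results = [
            decompose(est(0.1, 0.001), est(0.02, 0.0025), est(1.0, 1e-9),
                      mediator_id="reported"),
            decompose(est(0.1, 0.001), est(-0.02, 0.0025), est(1.0, 1e-9),
                      mediator_id="suppressed"),
        ]
        frame = mediation_frame(results)
        assert list(frame["mediated_proportion_pct"]) == ["20.00", "\\"]
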
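"""Stratified-population oracle: risks, counterfactuals and RR summaries."""

import json
import math

import pytest

from pafkit import (
    InvalidPopulationError,
    MissingReferenceCellError,
    StratifiedPopulation,
    StratumCell,
    ZeroRiskError,
)


def pop_from(rows, **kwargs):
    return StratifiedPopulation([StratumCell(*r) for r in rows], **kwargs)


NO_EFFECT = pop_from(
    [("a", 0, 0.4, 0.1), ("a", 1, 0.2, 0.1), ("b", 0, 0.3, 0.3), ("b", 1, 0.1, 0.3)]
)


class TestWorkedExample:
    """Hand-checkable summaries of the two packaged populations."""

    @pytest.mark.parametrize(
        "fixture_name, expected",
        [
            (
                "table1",
                dict(
                    observed=0.15,
                    counterfactual=0.12,
                    paf=0.2,
                    pi=0.45,
                    pi_c=0.6,
                    rr_u=11 / 6,
                    rr_c=1.5,
                    rr_e=1.5,
                ),
            ),
            (
                "table1_em",
                dict(
                    observed=0.195,
                    counterfactual=0.12,
                    paf=5 / 13,
                    pi=0.45,
                    pi_c=9 / 13,
                    rr_u=2.75,
                    rr_c=2.0,
                    rr_e=2.25,
                ),
            ),
        ],
    )
    def test_summaries(self, fixture_name, expected, request):
        pop = request.getfixturevalue(fixture_name)
        assert pop.observed_risk() == pytest.approx(expected["observed"], abs=1e-15)
        assert pop.counterfactual_risk() == pytest.approx(
            expected["counterfactual"], abs=1e-15
        )
        assert pop.paf() == pytest.approx(expected["paf"], abs=1e-15)
        assert pop.exposure_prevalence() == pytest.approx(expected["pi"], abs=1e-15)
        assert pop.case_prevalence() == pytest.approx(expected["pi_c"], abs=1e-15)
        assert pop.unadjusted_rr() == pytest.approx(expected["rr_u"], abs=1e-12)
        assert pop.marginal_causal_rr() == pytest.approx(expected["rr_c"], abs=1e-12)
        assert pop.causal_rr_exposed() == pytest.approx(expected["rr_e"], abs=1e-12)

    def test_stratum_rrs(self, table1, table1_em):
        assert table1.stratum_rrs() == pytest.approx(
            {"high_activity": 1.5, "low_activity": 1.5}
        )
        assert table1_em.stratum_rrs() == pytest.approx(
            {"high_activity": 1.5, "low_activity": 3.0}
        )

    def test_case_weighted_identity_matches_definition(self, table1, table1_em):
        # the case-weighted stratum decomposition is an exact identity
        for pop in (table1, table1_em):
            assert pop.paf_effect_modification() == pytest.approx(
                pop.paf(), abs=1e-12
            )

    def test_exposed_rr_identity(self, table1_em):
        # pi_c * (RR_e - 1)/RR_e recovers the definition PAF even under
        # effect modification (Miettinen's exposed-RR identity)
        rr_e = table1_em.causal_rr_exposed()
        val = table1_em.case_prevalence() * (rr_e - 1) / rr_e
        assert val == pytest.approx(table1_em.paf(), abs=1e-12)


class TestDegenerateAndEdgeCases:
    def test_single_cell_population(self):
        pop = pop_from([("only", 0, 1.0, 0.37)])
        assert pop.observed_risk() == 0.37
        assert pop.counterfactual_risk() == 0.37
        assert pop.paf() == 0.0
        assert pop.exposure_prevalence() == 0.0
        assert pop.case_prevalence() == 0.0

    def test_no_effect_population(self):
        assert NO_EFFECT.paf() == pytest.approx(0.0, abs=1e-15)
        assert NO_EFFECT.marginal_causal_rr() == pytest.approx(1.0)
        assert NO_EFFECT.causal_rr_exposed() == pytest.approx(1.0)
        assert NO_EFFECT.paf_effect_modification() == pytest.approx(0.0, abs=1e-15)

    def test_counterfactual_at_observed_level_is_observed(self, table1):
        # if everyone is already at the target level nothing is replaced
        pop = pop_from([("a", 0, 0.6, 0.2), ("b", 0, 0.4, 0.1)])
        assert pop.counterfactual_risk(0) == pop.observed_risk()

    def test_protective_exposure_gives_negative_paf(self):
        pop = pop_from(
            [("a", 0, 0.5, 0.2), ("a", 1, 0.5, 0.1)]
        )
        assert pop.paf() < 0  # returned as-is, never clamped
        assert pop.paf_effect_modification() == pytest.approx(pop.paf(), abs=1e-12)

    def test_zero_observed_risk_raises(self):
        pop = pop_from([("a", 0, 0.5, 0.0), ("a", 1, 0.5, 0.0)])
        with pytest.raises(ZeroRiskError):
            pop.paf()

    def test_stratum_missing_nonreference_level_is_allowed(self):
        pop = pop_from(
            [("a", 0, 0.5, 0.1), ("a", 1, 0.2, 0.2), ("b", 0, 0.3, 0.3)]
        )
        assert pop.exposure_prevalence() == pytest.approx(0.2)
        # but the marginal causal RR then needs the missing cell
        with pytest.raises(MissingReferenceCellError):
            pop.marginal_causal_rr(1)

    def test_exchangeable_population_unadjusted_equals_causal(self):
        # exposure independent of the confounder => RR_U == marginal RR_C
        pop = pop_from(
            [
                ("a", 0, 0.42, 0.1),
                ("a", 1, 0.28, 0.15),
                ("b", 0, 0.18, 0.2),
                ("b", 1, 0.12, 0.3),
            ]
        )
        assert pop.unadjusted_rr() == pytest.approx(
            pop.marginal_causal_rr(), abs=1e-12
        )

    def test_rr_summaries_bracketed_by_stratum_rrs(self, table1_em):
        # marginal and exposed causal RRs are weighted averages of the
        # stratum-specific causal RRs
        rrs = list(table1_em.stratum_rrs().values())
        for rr in (table1_em.marginal_causal_rr(), table1_em.causal_rr_exposed()):
            assert min(rrs) <= rr <= max(rrs)


class TestValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(InvalidPopulationError, match="sum"):
            pop_from([("a", 0, 0.5, 0.1), ("a", 1, 0.4, 0.2)])

    def test_normalize_flag_rescales(self):
        pop = pop_from(
            [("a", 0, 1.0, 0.1), ("a", 1, 1.0, 0.2)], normalize=True
        )
        assert sum(c.proportion for c in pop.cells) == pytest.approx(1.0)

    def test_duplicate_cell_rejected(self):
        with pytest.raises(InvalidPopulationError, match="duplicate"):
            pop_from([("a", 0, 0.5, 0.1), ("a", 0, 0.5, 0.2)])

    def test_missing_reference_cell_names_stratum(self):
        with pytest.raises(MissingReferenceCellError, match="'b'"):
            pop_from([("a", 0, 0.5, 0.1), ("b", 1, 0.5, 0.2)])

    @pytest.mark.parametrize(
        "cell",
        [
            ("a", 0, -0.1, 0.1),
            ("a", 0, 0.5, 1.5),
            ("a", -1, 0.5, 0.1),
        ],
    )
    def test_invalid_cell_rejected(self, cell):
        with pytest.raises(InvalidPopulationError):
            StratumCell(*cell)


class TestIO:
    def test_csv_round_trip(self, table1, tmp_path):
        path = tmp_path / "pop.csv"
        table1.to_csv(path)
        back = StratifiedPopulation.from_csv(path)
        assert back.to_dataframe().equals(table1.to_dataframe())

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("stratum,exposure,proportion\na,0,1.0\n")
        with pytest.raises(InvalidPopulationError, match="risk"):
            StratifiedPopulation.from_csv(path)

    def test_summaries_json_has_full_precision_and_rounded_block(self, table1):
        doc = json.loads(table1.summaries().to_json())
        assert doc["rr_u"] == pytest.approx(11 / 6, abs=1e-12)
        assert doc["rounded"]["rr_u"] == 1.83
        assert doc["rounded"]["paf"] == 0.2
        assert math.isclose(doc["paf"], 0.2, abs_tol=1e-15)
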
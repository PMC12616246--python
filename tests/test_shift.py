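import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenoscape.celltable import CellTable
from phenoscape.shift import (
    ShiftResult,
    StateThresholds,
    cell_state_counts,
    classify_cell_state,
    compute_shift,
    cytotoxicity_summary,
    fraction_positive,
    kendall_tau,
    percent_change_positive,
    signed_emd,
    therapeutic_apoptosis,
    xbar_emd,
)


def emd_oracle(a, b):
    """Independent oracle for equal-size samples: mean |sorted difference|."""
    return float(np.mean(np.abs(np.sort(a) - np.sort(b))))


class TestSignedEmd:
    def test_identity_is_zero(self):
        x = np.array([0.3, 1.2, 5.0])
        assert signed_emd(x, x) == 0.0

    def test_worked_example_and_antisymmetry(self):
        test, ref = [1, 1, 2, 2], [0, 0, 1, 1]
        assert signed_emd(test, ref) == pytest.approx(1.0, abs=1e-12)
        assert signed_emd(ref, test) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_sorted_difference_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(2, 500)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), n)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.1, 3), n)
            assert abs(abs(signed_emd(a, b)) - emd_oracle(a, b)) < 1e-9

    @given(
        x=st.lists(st.floats(-100, 100), min_size=2, max_size=50),
        c=st.floats(0.01, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_translation_property(self, x, c):
        x = np.array(x)
        assert signed_emd(x + c, x) == pytest.approx(c, rel=1e-9, abs=1e-9)

    def test_scale_property(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 100), rng.normal(1, 2, 100)
        base = signed_emd(a, b)
        assert signed_emd(3 * a, 3 * b) == pytest.approx(3 * base, rel=1e-9)

    def test_unequal_sizes_exact(self):
        # W1 between empirical [0,1] and [0,0,3]: quantile integral
        a, b = np.array([0.0, 1.0]), np.array([0.0, 0.0, 3.0])
        # oracle by fine common quantile grid
        qs = np.linspace(0, 1, 60001)[:-1] + 0.5 / 60001
        oracle = np.mean(np.abs(np.quantile(a, qs, method="inverted_cdf")
                                - np.quantile(b, qs, method="inverted_cdf")))
        assert abs(signed_emd(a, b)) == pytest.approx(oracle, abs=1e-3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            signed_emd([], [1.0])

    def test_tied_median_keeps_positive_sign(self):
        a = np.array([-1.0, 0.0, 1.0])
        b = np.array([-2.0, 0.0, 2.0])
        assert signed_emd(a, b) > 0


class TestXbarEmd:
    def test_definition(self):
        r = ShiftResult("c", "ref", {"a": 2.0, "b": -1.0, "c": 0.0})
        assert xbar_emd(r) == pytest.approx(1.0, abs=1e-12)
        assert r.xbar_emd == pytest.approx(1.0)
        assert r.abs_emd == {"a": 2.0, "b": 1.0, "c": 0.0}

    def test_null_and_lower_bound(self):
        assert xbar_emd({"a": 0.0, "b": 0.0}) == 0.0
        signed = {"a": 2.0, "b": -1.0}
        assert xbar_emd(signed) >= abs(np.mean(list(signed.values())))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            xbar_emd({})

    def test_recovers_planted_mean_shift(self, shifted_experiment):
        from phenoscape.preprocessing import arcsinh_transform

        table, truth = shifted_experiment
        t = arcsinh_transform(table)
        res = compute_shift(
            t.where_condition("treated"), t.where_condition("control"), markers=["pSTAT3"]
        )
        assert res.signed_emd["pSTAT3"] == pytest.approx(1.0, rel=0.05)


class TestFractions:
    def test_fraction_positive_examples(self):
        assert fraction_positive([0, 0, 2, 4], 1) == 0.5
        assert fraction_positive([0, 0], 5) == 0.0
        assert fraction_positive([0, 0], -np.inf) == 1.0

    def test_therapeutic_apoptosis_arithmetic(self):
        co = _cparp_table([3.0] * 55 + [0.0] * 45)
        mono = _cparp_table([3.0] * 20 + [0.0] * 80)
        assert therapeutic_apoptosis(co, mono, "cPARP", 1.0) == pytest.approx(35.0)
        assert therapeutic_apoptosis(co, co, "cPARP", 1.0) == 0.0

    def test_therapeutic_apoptosis_empty_gate_names_sample(self):
        co = _cparp_table([])
        with pytest.raises(ValueError, match="coculture"):
            therapeutic_apoptosis(co, _cparp_table([1.0]), "cPARP", 0.5)

    def test_percent_change_positive(self):
        t30 = _cparp_table([3.0] * 30 + [0.0] * 70)
        t20 = _cparp_table([3.0] * 20 + [0.0] * 80)
        t10 = _cparp_table([3.0] * 10 + [0.0] * 90)
        t40 = _cparp_table([3.0] * 40 + [0.0] * 60)
        assert percent_change_positive(t30, t20, "cPARP", 1.0) == pytest.approx(50.0)
        assert percent_change_positive(t20, t20, "cPARP", 1.0) == 0.0
        assert percent_change_positive(t10, t40, "cPARP", 1.0) == pytest.approx(-75.0)
        zero = _cparp_table([0.0] * 10)
        assert np.isnan(percent_change_positive(t30, zero, "cPARP", 1.0))


def _cparp_table(values) -> CellTable:
    return CellTable(pd.DataFrame({"cPARP": values}), {"cPARP": "state"})


class TestCellStates:
    def _table(self, cparp, idu, prb):
        return CellTable(
            pd.DataFrame({"cPARP": cparp, "IdU": idu, "pRB": prb}),
            {"cPARP": "state", "IdU": "state", "pRB": "state"},
        )

    def test_hierarchy(self):
        t = self._table([3.0, 0.0, 0.0, 0.0], [3.0, 0.0, 3.0, 0.0], [3.0, 0.0, 3.0, 3.0])
        states = classify_cell_state(t, StateThresholds(1.0, 1.0, 1.0))
        assert list(states) == ["apoptotic", "G0", "S", "other"]

    def test_counts_sum_to_population(self):
        rng = np.random.default_rng(0)
        t = self._table(rng.uniform(0, 4, 200), rng.uniform(0, 4, 200), rng.uniform(0, 4, 200))
        counts = cell_state_counts(t, StateThresholds(1.0, 1.0, 1.0))
        assert sum(counts.values()) == 200

    def test_missing_channel_is_configuration_error(self):
        t = _cparp_table([1.0])
        with pytest.raises(KeyError):
            classify_cell_state(t)

    def test_recovers_planted_state_fractions(self):
        from phenoscape.preprocessing import arcsinh_transform
        from phenoscape.synthetic import CytometrySimConfig, generate_cytometry_experiment

        config = CytometrySimConfig(
            conditions=["c"],
            cells_per_condition=4000,
            apoptosis_fraction={"c": 0.3},
            s_phase_fraction={"c": 0.25},
            seed=13,
        )
        table, truth = generate_cytometry_experiment(config)
        t = arcsinh_transform(table)
        states = classify_cell_state(t, StateThresholds(1.5, 1.5, 1.5))
        frac_apop = np.mean(states == "apoptotic")
        frac_s = np.mean(states == "S")
        assert frac_apop == pytest.approx(0.3, abs=0.02)
        assert frac_s == pytest.approx(0.25, abs=0.02)


class TestKendallTau:
    def test_perfect_concordance_and_discordance(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert kendall_tau(x, x) == pytest.approx(1.0)
        assert kendall_tau(x, x[::-1]) == pytest.approx(-1.0)

    def test_brute_force_pair_oracle(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        conc = disc = 0
        for (i, j) in itertools.combinations(range(4), 2):
            s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
            conc += s > 0
            disc += s < 0
        assert kendall_tau(x, y) == pytest.approx((conc - disc) / 6)
        assert kendall_tau(x, y) == pytest.approx(4 / 6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2, 3])
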
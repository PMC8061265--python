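"""Efficiency fitting, Pfaffl folds and the quantification pipeline."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cceamp import qpcr, simulate
from cceamp.errors import (
    FailedWellError,
    InsufficientCurveError,
    InvalidEfficiencyError,
    InvalidThresholdError,
    InvertedSeriesError,
    NoReferenceError,
)


def _curve(points):
    return qpcr.StandardCurve("g", points)


class TestFitStandardCurve:
    def test_perfect_doubling(self):
        est = qpcr.fit_standard_curve(
            _curve([(0, 20.0), (-1, 23.3219), (-2, 26.6439)])
        )
        assert est.efficiency == pytest.approx(2.0, abs=5e-5)
        assert est.slope == pytest.approx(-3.3219, abs=1e-3)
        assert est.r_squared > 0.999999

    def test_slope_345_closed_form(self):
        # points constructed with exact slope -3.45; E = 10**(1/3.45)
        est = qpcr.fit_standard_curve(_curve([(0, 20.0), (-1, 23.45), (-2, 26.90)]))
        assert est.efficiency == pytest.approx(10 ** (1 / 3.45), rel=1e-9)

    def test_two_levels_insufficient(self):
        with pytest.raises(InsufficientCurveError):
            qpcr.fit_standard_curve(_curve([(0, 20.0), (-1, 23.3), (-1, 23.4)]))

    def test_inverted_series(self):
        with pytest.raises(InvertedSeriesError):
            qpcr.fit_standard_curve(_curve([(0, 26.0), (-1, 23.0), (-2, 20.0)]))

    @pytest.mark.parametrize("efficiency", [1.8, 1.9, 2.0])
    def test_recovers_known_efficiency_exactly(self, efficiency):
        slope = -1.0 / np.log10(efficiency)
        pts = [(d, 20.0 + slope * d) for d in (0.0, -1.0, -2.0, -3.0)]
        est = qpcr.fit_standard_curve(_curve(pts))
        assert est.efficiency == pytest.approx(efficiency, rel=1e-9)


class TestPfafflFold:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((2.0, 5.0, 2.0, 0.0), 32.0),
            ((2.0, 0.0, 2.0, 0.0), 1.0),
            ((1.9, 3.0, 2.0, 1.0), 1.9**3 / 2.0),
        ],
    )
    def test_closed_form(self, args, expected):
        assert qpcr.pfaffl_fold(*args) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad_e", [0.9, 1.0, 2.3, -1.0])
    def test_efficiency_out_of_range(self, bad_e):
        with pytest.raises(InvalidEfficiencyError):
            qpcr.pfaffl_fold(bad_e, 1.0, 2.0, 1.0)

    @given(
        dcq_t=st.floats(-10, 10),
        dcq_r=st.floats(-10, 10),
    )
    def test_classic_ddct_when_both_efficiencies_two(self, dcq_t, dcq_r):
        fold = qpcr.pfaffl_fold(2.0, dcq_t, 2.0, dcq_r)
        assert fold == pytest.approx(2.0 ** (dcq_t - dcq_r), rel=1e-9)

    @given(
        dcq=st.floats(-5, 5),
        delta=st.floats(0.01, 3),
        e=st.floats(1.5, 2.2),
    )
    def test_monotone_in_target_and_reference_shifts(self, dcq, delta, e):
        base = qpcr.pfaffl_fold(e, dcq, e, 0.0)
        assert qpcr.pfaffl_fold(e, dcq + delta, e, 0.0) > base
        assert qpcr.pfaffl_fold(e, dcq, e, delta) < base


class TestCombineReferences:
    @pytest.mark.parametrize(
        "folds, expected", [([4, 9], 6.0), ([7.3], 7.3), ([2, 4, 8], 4.0)]
    )
    def test_geometric_mean(self, folds, expected):
        assert qpcr.combine_references(folds) == pytest.approx(expected, rel=1e-12)

    def test_empty_and_nonpositive(self):
        with pytest.raises(NoReferenceError):
            qpcr.combine_references([])
        with pytest.raises(NoReferenceError):
            qpcr.combine_references([2.0, 0.0])

    @given(
        folds=st.lists(st.floats(0.01, 100), min_size=1, max_size=6),
        scale=st.floats(0.1, 10),
    )
    def test_permutation_invariant_and_homogeneous(self, folds, scale):
        g = qpcr.combine_references(folds)
        assert qpcr.combine_references(folds[::-1]) == pytest.approx(g, rel=1e-9)
        assert qpcr.combine_references([scale * f for f in folds]) == pytest.approx(
            scale * g, rel=1e-9
        )


def _noiseless_run(truth, efficiency=2.0):
    spec = simulate.QpcrSimSpec(
        truths={
            "S1": {"TARGET": truth, "REF1": 1.0, "REF2": 1.0},
            "CAL": {"TARGET": 1.0, "REF1": 1.0, "REF2": 1.0},
        },
        efficiencies={g: efficiency for g in ("TARGET", "REF1", "REF2")},
        baseline_cq={"TARGET": 24.0, "REF1": 24.0, "REF2": 24.0},
        sigma_cq=0.0,
        replicates=2,
        seed=1,
        reference_genes=("REF1", "REF2"),
        calibrator_samples=("CAL",),
    )
    table = simulate.gen_qpcr(spec)
    eff = {g: efficiency for g in ("TARGET", "REF1", "REF2")}
    return qpcr.quantify(table, eff, ("CAL",), ["TARGET"], ["REF1", "REF2"])


class TestQuantify:
    def test_noiseless_roundtrip_truth_32(self):
        res = _noiseless_run(32.0)
        fold = res.loc[res.sample_id == "S1", "fold"].iloc[0]
        assert fold == pytest.approx(32.0, rel=1e-12)

    def test_calibrator_fold_is_one(self):
        res = _noiseless_run(32.0)
        assert res.loc[res.sample_id == "CAL", "fold"].iloc[0] == pytest.approx(
            1.0, rel=1e-12
        )

    def test_target_five_cycles_below_calibrator(self):
        rows = []
        for sample, cqs in {
            "CAL": {"T": 25.0, "R1": 22.0, "R2": 22.0},
            "S": {"T": 20.0, "R1": 22.0, "R2": 22.0},
        }.items():
            for gene, cq in cqs.items():
                role = "target" if gene == "T" else "reference"
                rows.append((sample, gene, role, "SYBR", 1, cq))
        table = pd.DataFrame(
            rows,
            columns=["sample_id", "gene_id", "gene_role", "dye", "replicate", "cq"],
        )
        res = qpcr.quantify(
            table, {"T": 2.0, "R1": 2.0, "R2": 2.0}, ("CAL",), ["T"], ["R1", "R2"]
        )
        assert res.loc[res.sample_id == "S", "fold"].iloc[0] == pytest.approx(32.0)

    def test_undetermined_target_reported_zero_with_flag(self):
        table = pd.DataFrame(
            [
                ("CAL", "T", "target", "SYBR", 1, 25.0),
                ("CAL", "R1", "reference", "SYBR", 1, 22.0),
                ("S", "T", "target", "SYBR", 1, np.nan),
                ("S", "R1", "reference", "SYBR", 1, 22.0),
            ],
            columns=["sample_id", "gene_id", "gene_role", "dye", "replicate", "cq"],
        )
        res = qpcr.quantify(table, {"T": 2.0, "R1": 2.0}, ("CAL",), ["T"], ["R1"])
        row = res[res.sample_id == "S"].iloc[0]
        assert row["fold"] == 0.0
        assert row["flag"] == "no-target-amplification"

    def test_sample_missing_all_references_skipped(self, caplog):
        table = pd.DataFrame(
            [
                ("CAL", "T", "target", "SYBR", 1, 25.0),
                ("CAL", "R1", "reference", "SYBR", 1, 22.0),
                ("S", "T", "target", "SYBR", 1, 20.0),
                ("S", "R1", "reference", "SYBR", 1, np.nan),
            ],
            columns=["sample_id", "gene_id", "gene_role", "dye", "replicate", "cq"],
        )
        res = qpcr.quantify(table, {"T": 2.0, "R1": 2.0}, ("CAL",), ["T"], ["R1"])
        assert "S" not in set(res["sample_id"])

    @pytest.mark.parametrize("efficiency", [1.8, 1.9, 2.0, 2.2])
    def test_roundtrip_identity_any_efficiency(self, efficiency):
        res = _noiseless_run(10.0, efficiency)
        fold = res.loc[res.sample_id == "S1", "fold"].iloc[0]
        assert fold == pytest.approx(10.0, rel=1e-9)


class TestDuplexQuantify:
    def test_five_cycle_shift(self):
        res = qpcr.duplex_quantify(25.0, 30.0, 2.0, 2.0, 30.0, 30.0)
        assert res.fold == pytest.approx(32.0)
        assert res.flag is None

    def test_identity(self):
        assert qpcr.duplex_quantify(30.0, 30.0, 2.0, 2.0, 30.0, 30.0).fold == 1.0

    def test_closed_form_195(self):
        res = qpcr.duplex_quantify(27.0, 29.0, 1.95, 1.95, 30.0, 30.0)
        assert res.fold == pytest.approx(1.95**3 / 1.95, rel=1e-12)

    def test_undetermined_fam_is_negative_well(self):
        res = qpcr.duplex_quantify(float("nan"), 30.0, 2.0, 2.0, 30.0, 30.0)
        assert res.fold == 0.0
        assert res.flag == "no-target-amplification"

    def test_undetermined_hex_fails_well(self):
        with pytest.raises(FailedWellError):
            qpcr.duplex_quantify(25.0, float("nan"), 2.0, 2.0, 30.0, 30.0)


class TestCallCq:
    @staticmethod
    def _trace(rng, rise_at=24.0):
        cycles = np.arange(1, 41, dtype=float)
        base = rng.normal(0.0, 1.0, cycles.size)
        signal = 1000.0 / (1.0 + np.exp(-(cycles - rise_at - 4.0)))
        return 50.0 + base + signal

    def test_interpolated_crossing_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        trace = self._trace(rng)
        got = qpcr.call_cq(trace)
        # independent brute-force oracle on the same trace
        base = trace[2:15]
        signal = trace - base.mean()
        thr = 10.0 * base.std(ddof=1)
        idx = next(
            i for i in range(1, 40) if signal[i - 1] < thr <= signal[i]
        )
        expected = idx + (thr - signal[idx - 1]) / (signal[idx] - signal[idx - 1])
        assert got == pytest.approx(expected, abs=1e-12)
        assert 20 < got < 35

    def test_flat_trace_undetermined(self):
        rng = np.random.default_rng(0)
        trace = 50.0 + rng.normal(0.0, 1.0, 40)
        assert qpcr.call_cq(trace) is None

    def test_zero_threshold_invalid(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InvalidThresholdError):
            qpcr.call_cq(self._trace(rng), threshold=0.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            qpcr.call_cq(np.zeros(20))
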
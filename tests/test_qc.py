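"""LOD, geometric-mean normalization factors, and lane-level QC rules."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nanomir as nm
from nanomir.errors import ConfigurationError, InsufficientControlsError, QCError
from nanomir.qc import (
    CONTENT_FLAG_RANGE,
    POS_FLAG_RANGE,
    apply_normalization,
    compute_lod,
    content_norm_factors,
    factor_flags,
    geometric_mean,
    lane_lods,
    lane_qc,
    positive_norm_factors,
)
from nanomir.rcc import LaneRecord, ProbeCount

from conftest import make_matrix


class TestComputeLod:
    def test_zero_variance_negatives_give_their_common_value(self):
        assert compute_lod([10, 10, 10, 10], k=2) == 10.0

    def test_matches_hand_computed_mean_plus_two_sample_sd(self):
        neg = [2, 4, 6, 8, 10, 12, 14, 16]
        expected = statistics.mean(neg) + 2 * statistics.stdev(neg)
        assert compute_lod(neg, k=2) == pytest.approx(expected, rel=1e-12)

    def test_k_zero_reduces_to_the_mean(self):
        neg = [3, 7, 11, 2]
        assert compute_lod(neg, k=0) == pytest.approx(statistics.mean(neg))

    def test_fewer_than_two_negatives_is_an_error(self):
        with pytest.raises(InsufficientControlsError):
            compute_lod([5], k=2)

    @given(
        neg=st.lists(st.integers(0, 100), min_size=2, max_size=10),
        k1=st.floats(0, 5),
        k2=st.floats(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_k(self, neg, k1, k2):
        lo, hi = sorted([k1, k2])
        assert compute_lod(neg, k=lo) <= compute_lod(neg, k=hi) + 1e-9

    @given(
        neg=st.lists(st.integers(0, 100), min_size=2, max_size=10),
        idx=st.integers(0, 9),
        bump=st.integers(1, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_k0_lod_nondecreasing_in_any_single_count(self, neg, idx, bump):
        idx %= len(neg)
        bumped = list(neg)
        bumped[idx] += bump
        assert compute_lod(bumped, k=0) >= compute_lod(neg, k=0)


class TestGeometricMean:
    def test_constant_input_returns_the_constant(self):
        assert geometric_mean([7.0, 7.0, 7.0]) == pytest.approx(7.0)

    def test_matches_exp_mean_log(self):
        expected = math.exp((math.log(1) + math.log(8)) / 2)
        assert geometric_mean([1, 8]) == pytest.approx(expected, rel=1e-12)

    def test_zero_replaced_by_one_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            value = geometric_mean([0, 8])
        assert value == pytest.approx(math.sqrt(8))
        assert "zero" in caplog.text

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            geometric_mean([])


def _pos_matrix(lane_counts: dict) -> nm.CountMatrix:
    """Positive-probe-only matrices for factor arithmetic."""
    names = ["POS_A", "POS_B", "NEG_A", "NEG_B"]
    classes = {"POS_A": "Positive", "POS_B": "Positive", "NEG_A": "Negative", "NEG_B": "Negative"}
    counts = {n: [lane_counts[l][i] for l in lane_counts] for i, n in enumerate(names)}
    design = {l: "g" for l in lane_counts}
    return make_matrix(counts, classes, design)


class TestNormFactors:
    def test_identical_lanes_give_factor_one_unflagged(self, toy_matrix):
        f = positive_norm_factors(toy_matrix)
        assert np.allclose(f, 1.0)
        assert not factor_flags(f, *POS_FLAG_RANGE).any()

    def test_doubled_lane_gives_closed_form_factors(self):
        m = _pos_matrix({"A": [100, 400, 10, 10], "B": [200, 800, 10, 10]})
        f = positive_norm_factors(m)
        assert f["A"] == pytest.approx(1.5)
        assert f["B"] == pytest.approx(0.75)

    def test_tenfold_lane_is_flagged_below_point_three(self):
        # five lanes, one scaled 10x: its factor is (n+9)/(10n) = 0.28 < 0.3
        lane_counts = {l: [100, 400, 10, 10] for l in "ABCD"}
        lane_counts["E"] = [1000, 4000, 10, 10]
        f = positive_norm_factors(_pos_matrix(lane_counts))
        flags = factor_flags(f, *POS_FLAG_RANGE)
        assert f["E"] == pytest.approx(0.28)
        assert flags["E"]

    def test_all_zero_positive_lane_is_qc_fatal(self):
        m = _pos_matrix({"A": [100, 400, 10, 10], "B": [0, 0, 10, 10]})
        with pytest.raises(QCError, match="B"):
            positive_norm_factors(m)

    def test_content_factors_match_brute_force_recomputation(self, toy_matrix):
        halved = toy_matrix.counts.copy()
        refs = ["ACTB", "B2M", "GAPDH", "RPL19", "RPLP0"]
        halved.loc[refs, "L1"] = halved.loc[refs, "L1"] // 2
        m = nm.CountMatrix(probes=toy_matrix.probes, counts=halved, design=toy_matrix.design)
        f = content_norm_factors(m)
        # brute force: arithmetic mean of per-lane reference geomeans / lane geomean
        geo = {
            lane: math.exp(np.log(halved.loc[refs, lane].astype(float)).mean())
            for lane in m.lanes
        }
        grand = sum(geo.values()) / len(geo)
        for lane in m.lanes:
            assert f[lane] == pytest.approx(grand / geo[lane], rel=1e-12)

    def test_missing_reference_gene_is_named(self, toy_matrix):
        m = nm.CountMatrix(
            probes=toy_matrix.probes.drop("RPL19"),
            counts=toy_matrix.counts.drop("RPL19"),
            design=toy_matrix.design,
        )
        with pytest.raises(ConfigurationError, match="RPL19"):
            content_norm_factors(m)

    @pytest.mark.parametrize(
        "value,rng,expected",
        [
            (0.3, POS_FLAG_RANGE, False),
            (3.0, POS_FLAG_RANGE, False),
            (0.29, POS_FLAG_RANGE, True),
            (3.01, POS_FLAG_RANGE, True),
            (0.1, CONTENT_FLAG_RANGE, False),
            (10.0, CONTENT_FLAG_RANGE, False),
            (12.0, CONTENT_FLAG_RANGE, True),
            (0.09, CONTENT_FLAG_RANGE, True),
        ],
    )
    def test_flag_boundaries_are_inclusive(self, value, rng, expected):
        assert bool(factor_flags(pd.Series([value]), *rng).iloc[0]) is expected

    def test_scale_invariance_of_both_factor_sets(self, default_matrix):
        scaled = nm.CountMatrix(
            probes=default_matrix.probes,
            counts=default_matrix.counts * 7,
            design=default_matrix.design,
        )
        pd.testing.assert_series_equal(
            positive_norm_factors(default_matrix), positive_norm_factors(scaled)
        )
        pd.testing.assert_series_equal(
            content_norm_factors(default_matrix), content_norm_factors(scaled)
        )

    def test_noise_free_lane_scale_recovery(self):
        # planted lognormal lane scales, exact (unrounded) counts: the
        # positive factor must invert the scale up to one global constant
        rng = np.random.default_rng(42)
        scales = np.exp(rng.normal(0, 0.4, size=6))
        base = {"POS_A": 32000.0, "POS_B": 8000.0, "NEG_A": 10.0, "NEG_B": 10.0}
        lane_counts = {
            f"L{i}": [base[n] * s for n in ("POS_A", "POS_B", "NEG_A", "NEG_B")]
            for i, s in enumerate(scales)
        }
        m = _pos_matrix(lane_counts)
        f = positive_norm_factors(m)
        products = np.array([f[f"L{i}"] * scales[i] for i in range(6)])
        assert products.max() / products.min() - 1 < 1e-6


class TestApplyNormalization:
    def test_unit_factors_are_identity(self, toy_matrix):
        ones = pd.Series(1.0, index=toy_matrix.lanes)
        norm = apply_normalization(toy_matrix, ones, ones)
        assert np.allclose(norm.counts, toy_matrix.counts)
        assert norm.provenance == ("positive", "content")

    def test_positive_stage_equalizes_spikein_geomeans(self, default_matrix):
        pos = positive_norm_factors(default_matrix)
        norm = apply_normalization(default_matrix, pos_factors=pos)
        pos_names = norm.names_of_class("Positive")
        geo = np.array(
            [geometric_mean(norm.counts.loc[pos_names, l]) for l in norm.lanes]
        )
        assert geo.max() / geo.min() - 1 < 1e-9

    def test_recomputed_factors_are_one_after_positive_stage(self, default_matrix):
        pos = positive_norm_factors(default_matrix)
        norm = apply_normalization(default_matrix, pos_factors=pos)
        renorm = nm.CountMatrix(
            probes=norm.probes, counts=norm.counts, design=norm.design
        )
        again = positive_norm_factors(renorm)
        assert np.abs(again - 1.0).max() < 1e-9


def _control_lane(pos_e=50, negatives=(10, 12), lig=(1980, 804, 311, 4, 5, 3)):
    probes = [
        ProbeCount("POS_A", "Positive", "A", 32000, 128.0),
        ProbeCount("POS_B", "Positive", "B", 8000, 32.0),
        ProbeCount("POS_C", "Positive", "C", 2000, 8.0),
        ProbeCount("POS_D", "Positive", "D", 500, 2.0),
        ProbeCount("POS_E", "Positive", "E", pos_e, 0.5),
        ProbeCount("POS_F", "Positive", "F", 31, 0.125),
    ]
    probes += [
        ProbeCount(f"NEG_{chr(65 + i)}", "Negative", "N", c)
        for i, c in enumerate(negatives)
    ]
    a, b, c, na, nb_, nc = lig
    probes += [
        ProbeCount("LIG_POS_A", "Ligation", "L", a),
        ProbeCount("LIG_POS_B", "Ligation", "L", b),
        ProbeCount("LIG_POS_C", "Ligation", "L", c),
        ProbeCount("LIG_NEG_A", "Ligation", "L", na),
        ProbeCount("LIG_NEG_B", "Ligation", "L", nb_),
        ProbeCount("LIG_NEG_C", "Ligation", "L", nc),
    ]
    return LaneRecord(lane_id="L", sample_attributes={}, probes=probes)


class TestLaneQC:
    def test_pos_e_above_background(self):
        qc = lane_qc(_control_lane(pos_e=50, negatives=(10, 12)), lod=16.0)
        assert qc.pose_above_background

    def test_pos_e_not_above_max_negative(self):
        qc = lane_qc(_control_lane(pos_e=11, negatives=(10, 12)), lod=16.0)
        assert not qc.pose_above_background

    def test_ligation_ordering_violation_fails(self):
        qc = lane_qc(_control_lane(lig=(400, 150, 200, 4, 5, 3)), lod=16.0)
        assert not qc.ligation_pass

    def test_ligation_negative_above_lod_fails(self):
        qc = lane_qc(_control_lane(lig=(1980, 804, 311, 30, 5, 3)), lod=16.0)
        assert not qc.ligation_pass

    def test_clean_lane_passes_ligation(self):
        qc = lane_qc(_control_lane(), lod=16.0)
        assert qc.ligation_pass

    def test_perfectly_proportional_titration_has_r2_one(self):
        lane = _control_lane()
        probes = []
        for p in lane.probes:
            if p.code_class == "Positive":
                # counts exactly proportional to concentration in log space
                count = int(p.nominal_concentration * 1000)
                probes.append(
                    ProbeCount(p.name, "Positive", p.accession, count, p.nominal_concentration)
                )
            else:
                probes.append(p)
        qc = lane_qc(LaneRecord("L", {}, probes), lod=16.0)
        assert qc.pos_linearity_r2 == pytest.approx(1.0, abs=1e-4)

    def test_missing_pos_e_is_a_qc_error(self):
        lane = _control_lane()
        probes = [p for p in lane.probes if p.name != "POS_E"]
        with pytest.raises(QCError, match="POS_E"):
            lane_qc(LaneRecord("L", {}, probes), lod=16.0)


def test_lane_lods_use_each_lanes_own_negatives(default_matrix):
    lods = lane_lods(default_matrix)
    neg = default_matrix.names_of_class("Negative")
    lane = default_matrix.lanes[3]
    expected = compute_lod(default_matrix.counts.loc[neg, lane], k=2)
    assert lods[lane] == pytest.approx(expected)
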
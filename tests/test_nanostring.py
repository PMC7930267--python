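import numpy as np
import pandas as pd
import pytest

from metnorm.errors import ValidationError
from metnorm.nanostring import (
    NormalizationParams,
    background_threshold,
    build_count_matrix,
    filter_low_expression,
    global_mean_normalize,
    normalize_counts,
    select_housekeeping,
)

from conftest import matrix_from_dict


def two_lane_matrix(neg_a, neg_b, endo_a, endo_b, extra=None):
    probes = {f"G{i}": "Endogenous" for i in range(len(endo_a))}
    probes.update({f"NEG_{i}": "Negative" for i in range(len(neg_a))})
    data = {
        "P1_PT": list(endo_a) + list(neg_a),
        "P1_LNM": list(endo_b) + list(neg_b),
    }
    index = list(probes)
    frame = {k: pd.Series(v, index=index) for k, v in data.items()}
    if extra:
        for name, (cls, va, vb) in extra.items():
            probes[name] = cls
            frame["P1_PT"][name] = va
            frame["P1_LNM"][name] = vb
    return matrix_from_dict(frame, probes)


class TestBackgroundThreshold:
    def test_all_zero_negatives_leave_counts_unchanged(self):
        m = two_lane_matrix([0, 0, 0], [0, 0, 0], [5, 100], [7, 3])
        out, thresholds = background_threshold(m)
        assert (thresholds == 0).all()
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_hand_computed_threshold_floors_low_counts(self):
        # negatives [10,12,14,10,14,12]: mean 12, sample SD sqrt(3.2)
        negs = [10, 12, 14, 10, 14, 12]
        t_expected = 12 + 2 * np.sqrt(3.2)  # ~= 15.5777
        m = two_lane_matrix(negs, negs, [14, 100], [14, 100])
        out, thresholds = background_threshold(m)
        assert thresholds["P1_PT"] == pytest.approx(t_expected, rel=1e-12)
        assert out.values.loc["G0", "P1_PT"] == pytest.approx(t_expected)
        assert out.values.loc["G1", "P1_PT"] == 100

    def test_multiplier_zero_gives_mean_and_monotonicity(self):
        negs = [4, 8, 12, 16]
        m = two_lane_matrix(negs, negs, [5, 50], [5, 50])
        out0, t0 = background_threshold(m, NormalizationParams(background_sd_multiplier=0))
        assert (t0 == 10).all()
        out2, _ = background_threshold(m, NormalizationParams(background_sd_multiplier=2))
        assert (out2.values.to_numpy() >= out0.values.to_numpy()).all()

    def test_negative_controls_themselves_unchanged(self):
        negs = [10, 12, 14, 10, 14, 12]
        m = two_lane_matrix(negs, negs, [1], [1])
        out, _ = background_threshold(m)
        neg_rows = [f"NEG_{i}" for i in range(6)]
        pd.testing.assert_frame_equal(out.values.loc[neg_rows], m.values.loc[neg_rows])

    def test_idempotent(self, small_cohort):
        m = build_count_matrix(small_cohort.samples)
        once, t1 = background_threshold(m)
        twice, t2 = background_threshold(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        pd.testing.assert_series_equal(t1, t2)

    def test_single_negative_probe_is_error(self):
        m = two_lane_matrix([5], [5], [10], [10])
        with pytest.raises(ValidationError, match="Negative probes"):
            background_threshold(m)


class TestSelectHousekeeping:
    def test_k_equals_all_returns_everything_in_stability_order(self):
        hk = {
            "HK_A": ("Housekeeping", 100, 100),
            "HK_B": ("Housekeeping", 100, 400),
        }
        m = two_lane_matrix([1, 2], [1, 2], [5], [5], extra=hk)
        assert select_housekeeping(m, k=2) == ["HK_A", "HK_B"]

    def test_constant_probe_beats_varying_probe(self):
        hk = {
            "HK_VAR": ("Housekeeping", 64, 256),
            "HK_CONST": ("Housekeeping", 128, 128),
        }
        m = two_lane_matrix([1, 2], [1, 2], [5], [5], extra=hk)
        assert select_housekeeping(m, k=1) == ["HK_CONST"]

    def test_planted_cv_ranking(self):
        """Six probes with increasing spread: the four tightest win."""
        rng = np.random.default_rng(0)
        n_samples = 40
        cvs = [0.01, 0.02, 0.05, 0.1, 0.2, 0.4]
        names = [f"HK{i}" for i in range(6)]
        probes = {n: "Housekeeping" for n in names}
        probes.update({"NEG_0": "Negative", "NEG_1": "Negative"})
        data = {}
        for j in range(n_samples):
            col = {}
            for name, cv in zip(names, cvs):
                log2v = rng.normal(10.0, 10.0 * cv)  # mean 10, CV as planted
                col[name] = 2.0 ** log2v
            col["NEG_0"] = 1
            col["NEG_1"] = 2
            data[f"P{j}_PT"] = pd.Series(col)
        m = matrix_from_dict(data, probes)
        assert set(select_housekeeping(m, k=4)) == set(names[:4])

    def test_too_few_candidates_is_error(self):
        m = two_lane_matrix([1, 2], [1, 2], [5], [5])
        with pytest.raises(ValidationError, match="at least k"):
            select_housekeeping(m, candidates=["G0"], k=2)


class TestGlobalMeanNormalize:
    def test_identical_lanes_are_untouched(self):
        hk = {"HK_A": ("Housekeeping", 100, 100), "POS_A": ("Positive", 50, 50)}
        m = two_lane_matrix([1, 2], [1, 2], [10], [10], extra=hk)
        out, factors = global_mean_normalize(m, ["HK_A", "POS_A"])
        assert factors["P1_PT"] == pytest.approx(1.0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_hand_geometric_mean_factors(self):
        # lane geometric means 10 and 40 -> grand mean 20, factors 2 and 0.5
        hk = {"HK_A": ("Housekeeping", 5, 20), "HK_B": ("Housekeeping", 20, 80)}
        m = two_lane_matrix([1, 2], [1, 2], [8], [8], extra=hk)
        out, factors = global_mean_normalize(m, ["HK_A", "HK_B"])
        assert factors["P1_PT"] == pytest.approx(2.0)
        assert factors["P1_LNM"] == pytest.approx(0.5)
        assert out.values.loc["G0", "P1_PT"] == pytest.approx(16.0)

    def test_scaling_one_whole_lane_is_invisible(self):
        hk = {"HK_A": ("Housekeeping", 50, 80), "POS_A": ("Positive", 200, 10)}
        m = two_lane_matrix([1, 2], [3, 4], [10, 30], [11, 29], extra=hk)
        out1, _ = global_mean_normalize(m, ["HK_A", "POS_A"])
        scaled = m.values.copy()
        scaled["P1_LNM"] = scaled["P1_LNM"] * 7.3
        m2 = matrix_from_dict(
            {c: scaled[c] for c in scaled.columns},
            m.code_class.to_dict(),
        )
        out2, _ = global_mean_normalize(m2, ["HK_A", "POS_A"])
        # the grand mean G absorbs a c**(1/n) shift, so the matrices agree
        # up to a single global constant; between-lane structure is intact
        ratio = out2.values / out1.values
        assert np.allclose(ratio.to_numpy(), ratio.iloc[0, 0], rtol=1e-12)

    def test_zero_normalizer_count_is_error(self):
        hk = {"HK_A": ("Housekeeping", 0, 10)}
        m = two_lane_matrix([1, 2], [1, 2], [5], [5], extra=hk)
        with pytest.raises(ValidationError, match="> 0"):
            global_mean_normalize(m, ["HK_A"])

    def test_equalizes_normalizer_geometric_means(self, small_cohort):
        """Post-normalization the normalizer geomean is lane-independent."""
        result = normalize_counts(small_cohort.samples)
        # recompute on the full (unfiltered) scale: scale factors applied to
        # the thresholded matrix must equalize the normalizer block
        m = build_count_matrix(small_cohort.samples)
        thresholded, _ = background_threshold(m)
        normalizers = thresholded.probes_of_class("Positive") + result.housekeeping
        block = thresholded.values.loc[normalizers].clip(lower=1.0)
        scaled = block.mul(result.scale_factors, axis=1)
        geomeans = np.exp(np.log(scaled).mean(axis=0))
        assert np.allclose(geomeans, geomeans.iloc[0], rtol=1e-9)


class TestFilterLowExpression:
    def make_normalized(self, gene_values):
        probes = {g: "Endogenous" for g in gene_values}
        data = {
            "P1_PT": pd.Series({g: v for g, (v, _) in gene_values.items()}),
            "P1_LNM": pd.Series({g: v for g, (_, v) in gene_values.items()}),
        }
        m = matrix_from_dict(data, probes)
        m.stage = "normalized"
        return m

    def test_boundary_is_strict(self):
        m = self.make_normalized({"AT64": (64, 64), "AT32": (32, 32)})
        out, excluded = filter_low_expression(m)
        assert list(out.values.index) == ["AT64"]  # mean log2 = 6 retained
        assert excluded == ["AT32"]  # mean log2 = 5 excluded

    def test_planted_straddle_set_recovered(self):
        rng = np.random.default_rng(3)
        means = {f"G{i}": 2.0 ** m for i, m in enumerate([3, 4, 5, 5.9, 6, 6.1, 7, 8, 9, 10])}
        gene_values = {g: (v, v) for g, v in means.items()}
        m = self.make_normalized(gene_values)
        out, excluded = filter_low_expression(m)
        assert excluded == ["G0", "G1", "G2", "G3"]

    def test_permutation_invariance(self):
        gene_values = {f"G{i}": (2.0 ** (4 + i), 2.0 ** (5 + i)) for i in range(6)}
        m = self.make_normalized(gene_values)
        out, excluded = filter_low_expression(m)
        shuffled = dict(reversed(list(gene_values.items())))
        m2 = self.make_normalized(shuffled)
        out2, excluded2 = filter_low_expression(m2)
        assert set(excluded) == set(excluded2)
        assert set(out.values.index) == set(out2.values.index)


def test_noise_free_chain_recovers_gene_means_up_to_constant():
    """counts = lane factor x gene mean: normalization undoes the lanes."""
    rng = np.random.default_rng(11)
    gene_means = {f"G{i}": 2.0 ** rng.uniform(7, 12) for i in range(30)}
    lanes = {f"P{j}_{t}": 2.0 ** rng.normal(0, 0.5) for j in range(4) for t in ("PT", "LNM")}
    probes = {g: "Endogenous" for g in gene_means}
    probes.update({"NEG_0": "Negative", "NEG_1": "Negative"})
    probes.update({f"POS_{i}": "Positive" for i in range(3)})
    probes.update({f"HK{i}": "Housekeeping" for i in range(4)})
    pos_means = {f"POS_{i}": 2.0 ** (8 + i) for i in range(3)}
    hk_means = {f"HK{i}": 2.0 ** (9 + 0.3 * i) for i in range(4)}
    data = {}
    for lane_id, f in lanes.items():
        col = {g: v * f for g, v in gene_means.items()}
        col["NEG_0"] = 0
        col["NEG_1"] = 0
        col.update({k: v * f for k, v in pos_means.items()})
        col.update({k: v * f for k, v in hk_means.items()})
        data[lane_id] = pd.Series(col)
    m = matrix_from_dict(data, probes)
    from metnorm.io_formats import ProbeRecord, SampleCounts

    samples = []
    for lane_id in data:
        probes_list = [
            ProbeRecord(name, probes[name], "", int(round(data[lane_id][name])))
            for name in data[lane_id].index
        ]
        patient, tissue = lane_id.split("_")
        samples.append(SampleCounts(lane_id, probes_list, patient, tissue))
    result = normalize_counts(samples)
    values = result.matrix.values
    ratio = values.div(pd.Series(gene_means).loc[values.index], axis=0)
    # each column is a single constant, and it is the same constant across lanes
    assert np.allclose(ratio.to_numpy(), ratio.to_numpy()[0, 0], rtol=1e-2)
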
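"""Sup-metric clustering, copy-number assignment, decoding, concordance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meltdose import calling
from meltdose.models import (
    GenotypeTruth,
    MeltdoseError,
    NegDerivCurve,
    PeakWindow,
    SampleCall,
)

GRID = 65.0 + 0.05 * np.arange(601)
WINDOW = PeakWindow("SMN1", 73.5, 1.5)


def _curve(height, sample_id, center=73.5, noise=0.0, seed=0):
    vals = height * np.exp(-0.5 * ((GRID - center) / 0.6) ** 2)
    vals += 10.0 * np.exp(-0.5 * ((GRID - 77.5) / 0.6) ** 2)
    if noise:
        vals += np.random.default_rng(seed).normal(0, noise, GRID.size)
    return NegDerivCurve(GRID, vals, sample_id)


class TestSupDistance:
    def test_identity(self):
        a = _curve(5.0, "a")
        assert calling.sup_distance(a, a, WINDOW) == 0.0

    def test_constant_offset_inside_window(self):
        a = _curve(5.0, "a")
        mask = (GRID >= WINDOW.low) & (GRID <= WINDOW.high)
        vals = a.values.copy()
        vals[mask] += 2.5
        b = NegDerivCurve(GRID, vals, "b")
        assert calling.sup_distance(a, b, WINDOW) == pytest.approx(2.5)

    def test_copy_number_distance_equals_height_gap(self):
        """1- vs 2-copy curves: the target peak dominates the sup."""
        one = _curve(5.0, "one")
        two = _curve(10.0, "two")
        d = calling.sup_distance(one, two, WINDOW)
        assert d == pytest.approx(5.0, rel=0.05)

    def test_mismatched_grids_rejected(self):
        a = _curve(5.0, "a")
        b = NegDerivCurve(GRID + 0.01, a.values, "b")
        with pytest.raises(MeltdoseError, match="grid"):
            calling.sup_distance(a, b, WINDOW)

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_metric_axioms(self, data):
        """Symmetry and triangle inequality on random curve triples."""
        n = 40
        t = 65 + 0.05 * np.arange(n)
        w = PeakWindow("x", t[n // 2], 0.5)
        draw = lambda name: NegDerivCurve(
            t,
            np.array(data.draw(st.lists(
                st.floats(-10, 10, allow_nan=False), min_size=n, max_size=n))),
            name,
        )
        a, b, c = draw("a"), draw("b"), draw("c")
        dab = calling.sup_distance(a, b, w)
        dba = calling.sup_distance(b, a, w)
        dac = calling.sup_distance(a, c, w)
        dcb = calling.sup_distance(c, b, w)
        assert dab == dba
        assert dab <= dac + dcb + 1e-9
        assert calling.sup_distance(a, a, w) == 0.0


class TestHierarchicalCluster:
    def test_two_well_separated_groups(self):
        curves = [_curve(10.0, f"a{i}") for i in range(3)]
        curves += [_curve(5.0, f"b{i}") for i in range(3)]
        result = calling.hierarchical_cluster(curves, WINDOW, controls={})
        labels = result.labels
        ga = {labels[f"a{i}"] for i in range(3)}
        gb = {labels[f"b{i}"] for i in range(3)}
        assert len(ga) == 1 and len(gb) == 1 and ga != gb

    def test_four_copy_levels_give_four_clusters(self):
        """Noiseless 0/1/2/3-copy heights separate into 4 clusters."""
        curves = []
        for copies, n in [(0, 3), (1, 4), (2, 4), (3, 2)]:
            for i in range(n):
                curves.append(_curve(5.0 * copies, f"c{copies}_{i}",
                                     noise=0.05, seed=copies * 10 + i))
        controls = {"c0_0": 0, "c1_0": 1, "c2_0": 2}
        result = calling.hierarchical_cluster(curves, WINDOW, controls)
        assert len(set(result.labels.values())) == 4
        for copies, n in [(0, 3), (1, 4), (2, 4), (3, 2)]:
            group = {result.labels[f"c{copies}_{i}"] for i in range(n)}
            assert len(group) == 1

    def test_single_class_batch_joins_matching_control(self):
        """All-normal batch: three clusters, samples with the 2-copy control."""
        curves = [_curve(10.0, "ctrl2"), _curve(5.0, "ctrl1"),
                  _curve(0.0, "ctrl0")]
        curves += [_curve(10.0, f"s{i}", noise=0.03, seed=i) for i in range(6)]
        controls = {"ctrl2": 2, "ctrl1": 1, "ctrl0": 0}
        result = calling.hierarchical_cluster(curves, WINDOW, controls)
        assert len(set(result.labels.values())) == 3
        for i in range(6):
            assert result.labels[f"s{i}"] == result.labels["ctrl2"]

    def test_inseparable_controls_fail_batch(self):
        a = _curve(5.0, "ctrl_a")
        b = NegDerivCurve(GRID, a.values.copy(), "ctrl_b")
        others = [_curve(5.0, f"s{i}") for i in range(2)]
        with pytest.raises(MeltdoseError, match="separated|failed"):
            calling.hierarchical_cluster(
                [a, b] + others, WINDOW, {"ctrl_a": 1, "ctrl_b": 2}
            )

    def test_partition_invariant_under_sample_order(self):
        rng = np.random.default_rng(9)
        curves = []
        for copies, n in [(1, 5), (2, 5)]:
            for i in range(n):
                curves.append(_curve(5.0 * copies, f"c{copies}_{i}",
                                     noise=0.1, seed=int(rng.integers(1e6))))
        res1 = calling.hierarchical_cluster(curves, WINDOW, {})
        perm = list(reversed(curves))
        res2 = calling.hierarchical_cluster(perm, WINDOW, {})

        def partition(labels):
            groups = {}
            for sid, lab in labels.items():
                groups.setdefault(lab, set()).add(sid)
            return {frozenset(g) for g in groups.values()}

        assert partition(res1.labels) == partition(res2.labels)


class TestAssignCopyNumbers:
    def _clusters(self, mapping):
        return calling.ClusterResult(mapping, np.array([0.1, 5.0]), 1.0)

    def test_control_anchoring(self):
        clusters = self._clusters({"ctrl1": 1, "s1": 1, "s2": 1})
        dosages = {"ctrl1": 0.5, "s1": 0.52, "s2": 0.48}
        out = calling.assign_copy_numbers(clusters, {"ctrl1": 1}, dosages)
        assert all(out[s].copies == 1 for s in dosages)
        assert not any(out[s].atypical for s in dosages)

    def test_control_free_cluster_rounds_doubled_median(self):
        """Median dosage 1.52 → round(3.04) = 3 copies (e.g. a duplication)."""
        clusters = self._clusters({"ctrl2": 1, "x1": 2, "x2": 2, "x3": 2})
        dosages = {"ctrl2": 1.0, "x1": 1.5, "x2": 1.52, "x3": 1.6}
        out = calling.assign_copy_numbers(clusters, {"ctrl2": 2}, dosages)
        assert out["x2"].copies == 3

    def test_dosage_conflict_flagged_atypical(self):
        clusters = self._clusters({"ctrl2": 1, "odd": 1})
        dosages = {"ctrl2": 1.0, "odd": 0.55}
        out = calling.assign_copy_numbers(clusters, {"ctrl2": 2}, dosages)
        assert out["odd"].atypical
        assert not out["ctrl2"].atypical

    def test_missing_control_rejected(self):
        clusters = self._clusters({"s1": 1})
        with pytest.raises(MeltdoseError, match="controls"):
            calling.assign_copy_numbers(clusters, {"ctrl": 2}, {"s1": 1.0})


class TestDecoding:
    @pytest.mark.parametrize("copies,phenotype", [
        (0, "SMA"), (1, "Carrier"), (2, "Normal"), (3, "No SMA"), (4, "No SMA"),
    ])
    def test_smn1_dosage_to_clinical_class(self, copies, phenotype):
        assert calling.decode_sma(copies) == phenotype

    @pytest.mark.parametrize("copies,label", [
        ((2, 2, 2), "Normal"),
        ((1, 2, 2), "LCR22A-B"),
        ((1, 1, 2), "LCR22A-C"),
        ((1, 1, 1), "LCR22A-D"),
        ((2, 1, 1), "LCR22B-D"),
        ((2, 1, 2), "Atypical"),
        ((0, 1, 1), "Atypical"),
    ])
    def test_hemizygosity_pattern_to_deletion_class(self, copies, label):
        assert calling.decode_del22q(copies) == label

    def test_decoding_total_over_domain(self):
        for a in range(4):
            for b in range(4):
                for c in range(4):
                    assert calling.decode_del22q((a, b, c)) in {
                        "Normal", "LCR22A-B", "LCR22A-C", "LCR22A-D",
                        "LCR22B-D", "Atypical",
                    }


class TestConcordance:
    def _truth(self, n, copies=2):
        return {
            f"s{i}": GenotypeTruth({"SMN1": copies}, "Normal") for i in range(n)
        }

    def _calls(self, n, copies=2):
        return [
            SampleCall(f"s{i}", {"SMN1": copies}, "Normal") for i in range(n)
        ]

    def test_perfect_agreement(self):
        rep = calling.concordance_report(self._calls(10), self._truth(10))
        assert rep.overall == 1.0
        assert rep.mismatches == []

    def test_one_mismatch_in_ten(self):
        calls = self._calls(10)
        calls[3] = SampleCall("s3", {"SMN1": 1}, "Carrier")
        rep = calling.concordance_report(calls, self._truth(10))
        assert rep.overall == pytest.approx(0.9)
        assert rep.mismatches == ["s3"]
        assert "s3" in rep.summary() or "90.0%" in rep.summary()

    def test_disjoint_ids_rejected(self):
        calls = self._calls(3)
        truth = self._truth(2)
        with pytest.raises(MeltdoseError, match="ids"):
            calling.concordance_report(calls, truth)
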
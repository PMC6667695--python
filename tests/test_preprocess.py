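"""Preprocessing stages: flooring, quantile normalization (against an
independent brute-force oracle), median-centering, annotation filtering,
probe collapsing, and normalization to untreated wild-type."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mkpatterns.containers import GeneMatrix
from mkpatterns.preprocess import (
    baseline_to_median,
    collapse_probes,
    filter_annotated,
    floor_intensities,
    normalize_to_untreated_wt,
    quantile_normalize,
)


def quantile_oracle(df: pd.DataFrame) -> pd.DataFrame:
    """Brute-force sort/average-by-rank reference: per column, every value is
    replaced by the mean of the per-rank column means over its rank span."""
    vals = df.to_numpy(dtype=float)
    n, m = vals.shape
    mu = np.mean(np.sort(vals, axis=0), axis=1)
    out = np.empty_like(vals)
    for j in range(m):
        col = vals[:, j].tolist()
        ordered = sorted(col)
        for i, v in enumerate(col):
            lo = ordered.index(v)
            hi = lo + ordered.count(v) - 1
            out[i, j] = mu[lo : hi + 1].mean()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


class TestFloor:
    @pytest.mark.parametrize("value,expected", [(4.2, 5.0), (5.0, 5.0), (-10.0, 5.0), (7.3, 7.3)])
    def test_examples(self, value, expected):
        df = pd.DataFrame({"s1": [value]})
        assert floor_intensities(df)["s1"].iloc[0] == expected

    @given(arrays(float, (6, 3), elements=st.floats(-100, 100)))
    def test_monotone_and_bounded(self, vals):
        out = floor_intensities(pd.DataFrame(vals)).to_numpy()
        assert (out >= 5.0).all()
        # monotone: sorting the inputs sorts the outputs
        order = np.argsort(vals, axis=0, kind="stable")
        for j in range(3):
            assert (np.diff(out[order[:, j], j]) >= 0).all()
        # values already at or above the floor pass through unchanged
        assert np.array_equal(out[vals >= 5.0], vals[vals >= 5.0])

    def test_rejects_nonpositive_floor(self):
        with pytest.raises(ValueError):
            floor_intensities(pd.DataFrame({"s1": [1.0]}), floor=0)


class TestQuantileNormalize:
    def test_two_column_example(self):
        df = pd.DataFrame({"a": [5.0, 3.0, 8.0], "b": [6.0, 2.0, 9.0]})
        out = quantile_normalize(df)
        assert out["a"].tolist() == [5.5, 2.5, 8.5]
        assert out["b"].tolist() == [5.5, 2.5, 8.5]

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        assert quantile_normalize(df).equals(df)

    def test_ties_get_rank_span_mean(self):
        df = pd.DataFrame({"a": [4.0, 4.0, 10.0], "b": [2.0, 6.0, 9.0]})
        out = quantile_normalize(df)
        # reference quantiles: [(4+2)/2, (4+6)/2, (10+9)/2] = [3, 5, 9.5]
        assert out["a"].tolist() == [4.0, 4.0, 9.5]
        assert out["b"].tolist() == [3.0, 5.0, 9.5]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame())

    def test_sorted_columns_identical_and_sum_preserved(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(3, 1, (40, 5)))
        out = quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.allclose(np.sort(out[:, j]), ref)
        assert np.isclose(out.sum(), 5 * ref.sum())

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = rng.integers(2, 21)
            m = rng.integers(2, 6)
            # integer draws force frequent ties
            df = pd.DataFrame(rng.integers(0, 8, (n, m)).astype(float))
            pd.testing.assert_frame_equal(quantile_normalize(df), quantile_oracle(df))


class TestBaselineToMedian:
    def test_constant_row_becomes_zeros(self):
        df = pd.DataFrame({"a": [4.0], "b": [4.0], "c": [4.0]})
        assert baseline_to_median(df).iloc[0].tolist() == [0.0, 0.0, 0.0]

    def test_hand_log2_arithmetic(self):
        df = pd.DataFrame({"a": [4.0], "b": [8.0], "c": [16.0]})
        assert baseline_to_median(df).iloc[0].tolist() == [-1.0, 0.0, 1.0]

    def test_idempotent_on_log2_scale(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.lognormal(2, 1, (10, 5)))
        once = baseline_to_median(df)
        twice = baseline_to_median(once, scale="log2")
        pd.testing.assert_frame_equal(once, twice)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            baseline_to_median(pd.DataFrame({"a": [0.0], "b": [1.0]}))


class TestFilterAnnotated:
    @staticmethod
    def annot(flags):
        return pd.DataFrame(
            {
                "probe_id": list(flags),
                "gene_symbol": [f"G{p}" for p in flags],
                "accession": [f"NM_{p}" for p in flags],
                "known_function": list(flags.values()),
            }
        )

    def test_all_annotated_is_identity(self):
        df = pd.DataFrame({"s": [1.0, 2.0]}, index=["p1", "p2"])
        out = filter_annotated(df, self.annot({"p1": 1, "p2": 1}))
        pd.testing.assert_frame_equal(out, df)

    def test_none_annotated_keeps_sample_header(self):
        df = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["p1"])
        out = filter_annotated(df, self.annot({"p1": 0}))
        assert len(out) == 0 and list(out.columns) == ["s1", "s2"]

    def test_mixed_preserves_relative_order(self):
        df = pd.DataFrame({"s": range(5)}, index=[f"p{i}" for i in range(5)], dtype=float)
        out = filter_annotated(df, self.annot({"p0": 1, "p1": 0, "p2": 1, "p3": 0, "p4": 1}))
        assert out.index.tolist() == ["p0", "p2", "p4"]

    def test_probes_absent_from_annotation_dropped(self):
        df = pd.DataFrame({"s": [1.0, 2.0]}, index=["p1", "unknown"])
        out = filter_annotated(df, self.annot({"p1": 1}))
        assert out.index.tolist() == ["p1"]


class TestCollapseProbes:
    def make(self, tiny_samples, probe_values, gene_of_probe):
        matrix = pd.DataFrame(probe_values).T
        matrix.columns = tiny_samples["sample_id"].tolist()
        annotation = pd.DataFrame(
            {
                "probe_id": list(probe_values),
                "gene_symbol": [gene_of_probe[p] for p in probe_values],
                "accession": ["x"] * len(probe_values),
                "known_function": [1] * len(probe_values),
            }
        )
        return matrix, annotation

    def wt_pattern(self, untr, lps, tiny_samples):
        """Probe row: wt untreated/LPS as given, other genotypes at 1."""
        row = []
        for s in tiny_samples.itertuples(index=False):
            if s.genotype == "wt":
                row.append(lps if s.treatment == "LPS" else untr)
            else:
                row.append(1.0)
        return row

    def test_highest_wt_induction_probe_kept(self, tiny_samples):
        values = {
            "pA": self.wt_pattern(10.0, 31.0, tiny_samples),   # 3.1x
            "pB": self.wt_pattern(10.0, 50.0, tiny_samples),   # 5.0x
        }
        matrix, annotation = self.make(tiny_samples, values, {"pA": "g1", "pB": "g1"})
        gm = collapse_probes(matrix, annotation, tiny_samples, timepoint=120)
        assert gm.probe_of_gene["g1"] == "pB"

    def test_single_probe_gene(self, tiny_samples):
        values = {"pA": self.wt_pattern(10.0, 31.0, tiny_samples)}
        matrix, annotation = self.make(tiny_samples, values, {"pA": "g1"})
        gm = collapse_probes(matrix, annotation, tiny_samples, timepoint=120)
        assert gm.probe_of_gene["g1"] == "pA"

    def test_exact_tie_broken_lexicographically(self, tiny_samples):
        values = {
            "pZ": self.wt_pattern(10.0, 40.0, tiny_samples),
            "pA": self.wt_pattern(20.0, 80.0, tiny_samples),   # same 4.0x induction
        }
        matrix, annotation = self.make(tiny_samples, values, {"pZ": "g1", "pA": "g1"})
        gm = collapse_probes(matrix, annotation, tiny_samples, timepoint=120)
        assert gm.probe_of_gene["g1"] == "pA"


class TestNormalizeToUntreatedWt:
    def test_ratio_and_self_normalization(self, tiny_samples):
        row = {s.sample_id: (200.0 if s.treatment == "untreated" and s.genotype == "wt" else 400.0)
               for s in tiny_samples.itertuples(index=False)}
        gm = GeneMatrix(values=pd.DataFrame([row], index=["g1"]), samples=tiny_samples)
        out = normalize_to_untreated_wt(gm)
        untr_wt = tiny_samples[(tiny_samples["genotype"] == "wt")
                               & (tiny_samples["treatment"] == "untreated")]["sample_id"]
        assert np.isclose(out.values[untr_wt.tolist()].mean(axis=1).iloc[0], 1.0)
        lps_wt = tiny_samples[(tiny_samples["genotype"] == "wt")
                              & (tiny_samples["treatment"] == "LPS")]["sample_id"]
        assert np.allclose(out.values[lps_wt.tolist()].iloc[0], 2.0)

    def test_invariant_under_global_rescaling(self, tiny_samples):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.lognormal(5, 1, (4, len(tiny_samples))),
                            columns=tiny_samples["sample_id"].tolist(),
                            index=[f"g{i}" for i in range(4)])
        out1 = normalize_to_untreated_wt(GeneMatrix(values=vals, samples=tiny_samples))
        out7 = normalize_to_untreated_wt(GeneMatrix(values=vals * 7.0, samples=tiny_samples))
        pd.testing.assert_frame_equal(out1.values, out7.values)

    def test_missing_untreated_wt_rejected(self, tiny_samples):
        no_wt = tiny_samples[tiny_samples["genotype"] != "wt"].reset_index(drop=True)
        vals = pd.DataFrame([[1.0] * len(no_wt)], columns=no_wt["sample_id"].tolist(), index=["g1"])
        with pytest.raises(ValueError, match="untreated wt"):
            normalize_to_untreated_wt(GeneMatrix(values=vals, samples=no_wt))
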
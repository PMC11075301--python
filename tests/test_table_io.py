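import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from menkit.errors import AnalysisError, FormatError
from menkit.table_io import (
    FeatureTable,
    filter_low_abundance,
    log_transform,
    prevalence_filter,
    rarefy,
    read_feature_table,
    write_feature_table,
)

from .conftest import make_table


class TestReadWrite:
    def test_round_trip(self, toy_table, tmp_path):
        tp, mp = tmp_path / "t.tsv", tmp_path / "m.tsv"
        write_feature_table(toy_table, tp, mp)
        back = read_feature_table(tp, mp)
        assert back.asv_ids == toy_table.asv_ids
        assert back.sample_ids == toy_table.sample_ids
        np.testing.assert_array_equal(back.counts, toy_table.counts)
        pd.testing.assert_frame_equal(back.metadata, toy_table.metadata)

    def test_missing_metadata_sample(self, toy_table, tmp_path):
        tp, mp = tmp_path / "t.tsv", tmp_path / "m.tsv"
        write_feature_table(toy_table, tp, mp)
        meta = pd.read_csv(mp, sep="\t").iloc[:-1]
        meta.to_csv(mp, sep="\t", index=False)
        with pytest.raises(FormatError, match="metadata missing"):
            read_feature_table(tp, mp)

    def test_non_integer_counts(self, toy_table, tmp_path):
        tp, mp = tmp_path / "t.tsv", tmp_path / "m.tsv"
        write_feature_table(toy_table, tp, mp)
        text = tp.read_text().replace("\t5\t", "\t1.5\t")
        tp.write_text(text)
        with pytest.raises(FormatError, match="non-integer"):
            read_feature_table(tp, mp)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(FormatError, match="duplicate ASV"):
            FeatureTable(np.zeros((2, 1), dtype=int), ["a", "a"], ["s"], None)

    def test_negative_counts_rejected(self):
        with pytest.raises(FormatError, match="negative"):
            FeatureTable(np.array([[-1]]), ["a"], ["s"], None)


class TestLowAbundanceFilter:
    def test_total_boundary(self):
        table = make_table([[9, 0, 0, 0], [4, 3, 2, 1]])
        out = filter_low_abundance(table, min_total=10, min_samples=3)
        assert out.asv_ids == ["ASV1"]

    def test_prevalence_boundary(self):
        # both reach min_total; only the first appears in >= 3 samples
        table = make_table([[4, 3, 3, 0], [10, 5, 0, 0]])
        out = filter_low_abundance(table, min_total=10, min_samples=3)
        assert out.asv_ids == ["ASV0"]

    def test_all_zero_table_warns_empty(self, caplog):
        table = make_table(np.zeros((2, 3), dtype=int))
        with caplog.at_level("WARNING"):
            out = filter_low_abundance(table)
        assert out.n_asv == 0

    def test_kept_if_passing_any_stratum(self):
        # fails in month 1 but passes in month 2
        table = make_table(
            [[1, 0, 0, 5, 5, 5]], months=[1, 1, 1, 2, 2, 2]
        )
        out = filter_low_abundance(table, min_total=10, min_samples=3)
        assert out.n_asv == 1

    def test_idempotent(self, rng):
        table = make_table(rng.integers(0, 5, size=(20, 6)))
        once = filter_low_abundance(table)
        twice = filter_low_abundance(once)
        assert once.asv_ids == twice.asv_ids
        np.testing.assert_array_equal(once.counts, twice.counts)


class TestPrevalenceFilter:
    def test_half_of_eight(self):
        counts = np.zeros((2, 8), dtype=int)
        counts[0, :4] = 1  # present in 4 of 8 -> kept
        counts[1, :3] = 1  # present in 3 of 8 -> removed
        out = prevalence_filter(make_table(counts), 0.5)
        assert out.asv_ids == ["ASV0"]

    def test_full_fraction(self):
        counts = np.array([[1, 1, 0], [1, 1, 1]])
        out = prevalence_filter(make_table(counts), 1.0)
        assert out.asv_ids == ["ASV1"]

    def test_tiny_fraction_is_identity(self):
        table = make_table([[1, 0], [0, 1]])
        out = prevalence_filter(table, 1e-9)
        assert out.asv_ids == table.asv_ids

    def test_idempotent(self, rng):
        table = make_table(rng.integers(0, 3, size=(30, 8)))
        once = prevalence_filter(table, 0.5)
        twice = prevalence_filter(once, 0.5)
        assert once.asv_ids == twice.asv_ids


class TestRarefy:
    def test_exact_depth(self, rng):
        table = make_table(rng.integers(0, 100, size=(30, 5)))
        out = rarefy(table, depth=200, seed=1)
        assert (out.counts.sum(axis=0) == 200).all()

    def test_shallow_sample_dropped(self):
        table = make_table([[10, 4], [10, 5]])
        out = rarefy(table, depth=10, seed=0)
        assert out.sample_ids == ["S0"]

    def test_deterministic(self, rng):
        table = make_table(rng.integers(0, 100, size=(30, 5)))
        a = rarefy(table, depth=150, seed=7)
        b = rarefy(table, depth=150, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_all_too_shallow_errors(self):
        table = make_table([[1], [1]])
        with pytest.raises(AnalysisError):
            rarefy(table, depth=10, seed=0)

    def test_unbiased_relative_abundance(self):
        # 1000-rep mean of a subsampled proportion ~ true proportion
        table = make_table([[300], [700]])
        props = [
            rarefy(table, depth=100, seed=s).counts[0, 0] / 100
            for s in range(1000)
        ]
        assert abs(np.mean(props) - 0.3) < 3 * 0.046 / np.sqrt(1000)


class TestLogTransform:
    def test_zero_maps_to_zero(self, toy_table):
        out = log_transform(toy_table)
        assert out.loc["ASV2", "S0"] == 0.0

    def test_count_99(self):
        out = log_transform(make_table([[99]]))
        assert out.iloc[0, 0] == pytest.approx(2.0)

    @settings(max_examples=25, deadline=None)
    @given(
        counts=arrays(
            np.int64, (4, 3), elements=st.integers(min_value=0, max_value=10_000)
        )
    )
    def test_monotone(self, counts):
        out = log_transform(make_table(counts)).to_numpy()
        order = np.argsort(counts.ravel())
        assert (np.diff(out.ravel()[order]) >= 0).all()
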
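"""Reading, normalization, imputation and filtering of count experiments."""

import numpy as np
import pandas as pd
import pytest

from rnasense import (
    ImputationError,
    NormalizationError,
    SchemaError,
    filter_threshold,
    impute_all_missing,
    impute_missing_sample,
    median_of_ratios_size_factors,
    normalize_sizefactors,
    read_experiment,
    write_experiment,
)
from rnasense.experiment import TimeCourseExperiment

from conftest import build_experiment


def _write_tables(tmp_path, counts: pd.DataFrame, meta: pd.DataFrame):
    cpath, mpath = tmp_path / "counts.tsv", tmp_path / "meta.tsv"
    counts.to_csv(cpath, sep="\t", index_label="gene")
    meta.to_csv(mpath, sep="\t", index=False)
    return cpath, mpath


@pytest.fixture
def toy_tables(tmp_path):
    counts = pd.DataFrame(
        {"s1": [1, 2, 3], "s2": [4, 5, 6], "s3": [7, 8, 9], "s4": [1, 1, 1]},
        index=["a", "b", "c"],
    )
    meta = pd.DataFrame(
        {
            "sample": ["s1", "s2", "s3", "s4"],
            "condition": ["WT", "WT", "MUT", "MUT"],
            "time_hpf": [2.5, 3.0, 2.5, 3.0],
            "replicate": [1, 1, 1, 1],
        }
    )
    return _write_tables(tmp_path, counts, meta)


class TestReadExperiment:
    def test_round_trip(self, toy_tables, tmp_path):
        exp = read_experiment(*toy_tables)
        assert exp.n_genes == 3 and exp.n_samples == 4
        assert list(exp.genes) == ["a", "b", "c"]
        write_experiment(exp, tmp_path / "c2.tsv", tmp_path / "m2.tsv")
        again = read_experiment(tmp_path / "c2.tsv", tmp_path / "m2.tsv")
        pd.testing.assert_frame_equal(exp.counts, again.counts)

    def test_unmapped_sample_column_is_schema_error(self, tmp_path):
        counts = pd.DataFrame({"s1": [1], "s2": [2]}, index=["a"])
        meta = pd.DataFrame(
            {"sample": ["s1"], "condition": ["WT"], "time_hpf": [2.5], "replicate": [1]}
        )
        with pytest.raises(SchemaError):
            read_experiment(*_write_tables(tmp_path, counts, meta))

    @pytest.mark.parametrize(
        "bad_counts",
        [
            pd.DataFrame({"s1": [-1], "s2": [2]}, index=["a"]),
            pd.DataFrame({"s1": ["x"], "s2": [2]}, index=["a"]),
            pd.DataFrame({"s1": [1, 2], "s2": [2, 3]}, index=["a", "a"]),
        ],
        ids=["negative", "non-numeric", "duplicate-gene"],
    )
    def test_invalid_counts_rejected(self, tmp_path, bad_counts):
        meta = pd.DataFrame(
            {
                "sample": ["s1", "s2"],
                "condition": ["WT", "WT"],
                "time_hpf": [2.5, 3.0],
                "replicate": [1, 1],
            }
        )
        with pytest.raises((ValueError, SchemaError)):
            read_experiment(*_write_tables(tmp_path, bad_counts, meta))


class TestNormalization:
    def _exp(self, counts: dict):
        meta = [(s, "WT", 2.5 + 0.5 * i, 1) for i, s in enumerate(counts)]
        return build_experiment(counts, meta)

    def test_identical_samples_have_unit_factors(self):
        exp = self._exp({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        out = normalize_sizefactors(exp)
        np.testing.assert_allclose(out.size_factors, [1.0, 1.0])
        pd.testing.assert_frame_equal(out.counts, exp.counts)

    def test_exact_scaling_case(self):
        exp = self._exp({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        out = normalize_sizefactors(exp)
        factors = out.size_factors.to_numpy()
        # factors proportional to (1, 2), geometric mean 1
        np.testing.assert_allclose(factors[1] / factors[0], 2.0)
        np.testing.assert_allclose(np.exp(np.log(factors).mean()), 1.0, atol=1e-6)
        np.testing.assert_allclose(out.counts["s1"], out.counts["s2"])

    def test_matches_per_gene_ratio_oracle(self):
        counts = {
            "s1": [5, 10, 40, 3, 7],
            "s2": [10, 18, 60, 9, 14],
            "s3": [20, 45, 100, 12, 30],
        }
        exp = self._exp(counts)
        frame = exp.counts
        # oracle: per-sample median over genes of count / geometric mean,
        # brought to unit geometric mean
        geo = np.exp(np.log(frame).mean(axis=1))
        expected = frame.div(geo, axis=0).median(axis=0)
        expected /= np.exp(np.log(expected).mean())
        got = median_of_ratios_size_factors(frame)
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_matches_deseq2_reference(self):
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(3)
        frame = pd.DataFrame(
            rng.integers(1, 500, size=(30, 4)).astype(float),
            columns=["s1", "s2", "s3", "s4"],
        )
        got = median_of_ratios_size_factors(frame)
        _, ref = deseq2_norm(frame.T)  # samples × genes convention
        ref = np.asarray(ref, dtype=float).ravel()
        ref /= np.exp(np.log(ref).mean())
        np.testing.assert_allclose(got.to_numpy(), ref, rtol=1e-8)

    def test_idempotent_to_tolerance(self):
        exp = self._exp({"s1": [5, 10, 40], "s2": [10, 18, 60], "s3": [20, 45, 100]})
        out = normalize_sizefactors(exp)
        refactors = median_of_ratios_size_factors(out.counts)
        np.testing.assert_allclose(refactors, 1.0, atol=1e-9)

    def test_no_all_positive_gene_raises_with_fallback_hint(self):
        exp = self._exp({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(NormalizationError, match="total-count"):
            normalize_sizefactors(exp)
        out = normalize_sizefactors(exp, fallback="total-count")
        assert out.normalized


class TestImputation:
    def _exp_with_gap(self, values_by_rep):
        counts, meta = {}, []
        for rep, vals in values_by_rep.items():
            for t, v in vals.items():
                sid = f"WT_r{rep}_t{t:g}"
                counts[sid] = v
                meta.append((sid, "WT", t, rep))
        return build_experiment(counts, meta)

    def test_mean_of_two_replicates(self):
        exp = self._exp_with_gap(
            {
                1: {5.5: [1.0], 6.0: [10.0]},
                2: {5.5: [2.0], 6.0: [20.0]},
                3: {5.5: [3.0]},  # missing 6.0 slot
            }
        )
        assert exp.missing_pairs() == [("WT", 6.0, 3)]
        out = impute_missing_sample(exp, "WT", 6.0)
        imputed = out.sample_ids("WT", 6.0)[-1]
        assert out.samples.loc[imputed, "imputed"]
        np.testing.assert_allclose(out.counts[imputed], [15.0])
        assert out.missing_pairs() == []

    def test_single_survivor(self):
        exp = self._exp_with_gap({1: {5.5: [1.0], 6.0: [7.0]}, 2: {5.5: [2.0]}})
        out = impute_missing_sample(exp, "WT", 6.0)
        np.testing.assert_allclose(out.counts[out.sample_ids("WT", 6.0)[-1]], [7.0])

    def test_existing_cells_untouched_and_grids_equalized(self, small_sim):
        exp, _ = small_sim
        before = exp.counts.copy()
        out = impute_all_missing(exp)
        pd.testing.assert_frame_equal(out.counts[before.columns], before)
        assert out.missing_pairs() == []
        grids = {
            cond: tuple(sorted(out.samples.loc[out.sample_ids(cond), "time_hpf"].unique()))
            for cond in out.conditions
        }
        assert len(set(grids.values())) == 1

    def test_not_missing_or_no_survivor(self):
        exp = self._exp_with_gap({1: {5.5: [1.0], 6.0: [7.0]}, 2: {5.5: [2.0]}})
        with pytest.raises(ValueError):
            impute_missing_sample(exp, "WT", 5.5)


class TestFilterThreshold:
    def _exp(self):
        counts = {"s1": [99.9, 100.0, 0.0], "s2": [50.0, 0.0, 150.0]}
        meta = [("s1", "WT", 2.5, 1), ("s2", "WT", 3.0, 1)]
        return build_experiment(counts, meta, normalized=True)

    def test_boundary_and_single_point_rule(self):
        out = filter_threshold(self._exp(), 100.0)
        # max 99.9 removed; a single sample at the threshold keeps the gene
        assert list(out.genes) == ["g1", "g2"]

    def test_zero_threshold_is_identity(self):
        exp = self._exp()
        out = filter_threshold(exp, 0.0)
        pd.testing.assert_frame_equal(out.counts, exp.counts)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_threshold(self._exp(), -1.0)

    def test_generator_truth_counts(self):
        # genes scripted below the cutoff are exactly the ones removed
        rng = np.random.default_rng(0)
        levels = np.concatenate([np.full(30, 150.0), np.full(20, 40.0)])
        counts = {
            f"s{j}": rng.poisson(levels).astype(float) * 0 + levels for j in range(3)
        }
        meta = [(f"s{j}", "WT", 2.5 + 0.5 * j, 1) for j in range(3)]
        exp = build_experiment(counts, meta, normalized=True)
        out = filter_threshold(exp, 100.0)
        assert out.n_genes == 30
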
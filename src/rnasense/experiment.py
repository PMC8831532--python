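"""Time-course count container: reading, normalization, imputation, filtering.

A :class:`TimeCourseExperiment` holds a genes × samples count matrix together
with per-sample metadata (condition, time in hours post-fertilization,
replicate index). Raw integer counts are made comparable across libraries
with median-of-ratios size factors; a missing replicate slot can be filled
with the mean of the surviving replicates at the same (condition, time) so
that every condition covers the same time grid; lowly expressed genes are
removed with a max-over-samples threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourseExperiment",
    "SchemaError",
    "NormalizationError",
    "ImputationError",
    "read_experiment",
    "write_experiment",
    "median_of_ratios_size_factors",
    "normalize_sizefactors",
    "impute_missing_sample",
    "impute_all_missing",
    "filter_threshold",
]

METADATA_COLUMNS = ("condition", "time_hpf", "replicate")


class SchemaError(ValueError):
    """Counts table and sample metadata do not describe the same samples."""


class NormalizationError(RuntimeError):
    """Size factors cannot be computed from this matrix."""


class ImputationError(RuntimeError):
    """No surviving replicate to impute from."""


@dataclass
class TimeCourseExperiment:
    """Genes × samples count matrix with sample annotations.

    ``counts`` columns and ``samples`` index are identical and ordered; the
    ``imputed`` metadata column flags pseudo-samples inserted by imputation.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if "imputed" not in self.samples.columns:
            self.samples = self.samples.assign(imputed=False)
        missing_cols = [c for c in METADATA_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise SchemaError(f"sample metadata lacks columns {missing_cols}")
        if list(self.counts.columns) != list(self.samples.index):
            unmapped = set(self.counts.columns) - set(self.samples.index)
            if unmapped:
                raise SchemaError(f"count columns without metadata: {sorted(unmapped)}")
            extra = set(self.samples.index) - set(self.counts.columns)
            if extra:
                raise SchemaError(f"metadata rows without count column: {sorted(extra)}")
            # same sets, different order: follow metadata order
            self.counts = self.counts[list(self.samples.index)]
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.isnan(values).any():
            raise ValueError("counts contain NaN")
        if (values < 0).any():
            raise ValueError("counts contain negative values")

    # ---- basic accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.samples["time_hpf"].unique())

    def sample_ids(
        self,
        condition: str | None = None,
        time: float | None = None,
        include_imputed: bool = True,
    ) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if time is not None:
            mask &= np.isclose(self.samples["time_hpf"].astype(float), time)
        if not include_imputed:
            mask &= ~self.samples["imputed"].astype(bool)
        return list(self.samples.index[mask])

    def values(
        self,
        condition: str | None = None,
        time: float | None = None,
        include_imputed: bool = True,
    ) -> pd.DataFrame:
        return self.counts[self.sample_ids(condition, time, include_imputed)]

    def missing_pairs(self) -> list[tuple[str, float, int]]:
        """(condition, time, replicate) slots absent from an otherwise full grid.

        A condition's expected replicate set is the union of replicate indices
        it shows anywhere on the grid; a slot is missing when that replicate
        has no sample at one of the condition's time points.
        """
        out = []
        times = self.times
        for cond in self.conditions:
            sub = self.samples[self.samples["condition"] == cond]
            reps = sorted(sub["replicate"].unique())
            for t in times:
                present = set(sub.loc[np.isclose(sub["time_hpf"].astype(float), t), "replicate"])
                for r in reps:
                    if r not in present:
                        out.append((cond, float(t), int(r)))
        return out


# ---- I/O -----------------------------------------------------------------


def read_experiment(counts_path: str | Path, metadata_path: str | Path) -> TimeCourseExperiment:
    """Read a genes × samples TSV and its sample sheet.

    The counts table has gene identifiers in the first column and one column
    per sample; the metadata TSV maps every sample column to
    (condition, time_hpf, replicate) via a ``sample`` column.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample" not in meta.columns:
        raise SchemaError("metadata lacks a 'sample' column")
    meta = meta.set_index("sample")
    if "imputed" in meta.columns:
        meta["imputed"] = meta["imputed"].astype(bool)
    try:
        counts = counts.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric counts in {counts_path}: {exc}") from None
    return TimeCourseExperiment(counts=counts, samples=meta)


def write_experiment(
    exp: TimeCourseExperiment, counts_path: str | Path, metadata_path: str | Path
) -> None:
    """Emit counts and metadata in the same TSV dialect ``read_experiment`` reads."""
    exp.counts.to_csv(counts_path, sep="\t", float_format="%.10g", index_label="gene")
    exp.samples.to_csv(metadata_path, sep="\t", index_label="sample")


# ---- normalization -------------------------------------------------------


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference = per-gene geometric mean over samples, computed on genes with
    all-positive counts; each sample's factor is the median over those genes
    of count/reference, rescaled to unit geometric mean so that normalization
    is idempotent (a second pass returns factors of exactly 1).
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError(
            "no gene has all-positive counts; median-of-ratios is undefined — "
            "fall back to total-count scaling (normalize_sizefactors(..., "
            "fallback='total-count'))"
        )
    logs = np.log(values[positive])
    log_ref = logs.mean(axis=1)
    log_factors = np.median(logs - log_ref[:, None], axis=0)
    factors = np.exp(log_factors - log_factors.mean())
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_sizefactors(
    exp: TimeCourseExperiment, fallback: str = "error"
) -> TimeCourseExperiment:
    """Divide each sample by its median-of-ratios size factor.

    ``fallback='total-count'`` scales by library totals (relative to their
    geometric mean) when no gene has all-positive counts.
    """
    if exp.normalized:
        raise ValueError("experiment is already normalized")
    if exp.n_samples < 2:
        raise ValueError("normalization requires at least 2 samples")
    try:
        factors = median_of_ratios_size_factors(exp.counts)
    except NormalizationError:
        if fallback != "total-count":
            raise
        totals = exp.counts.sum(axis=0).astype(float)
        if (totals <= 0).any():
            raise NormalizationError("empty library; cannot scale by totals") from None
        factors = totals / np.exp(np.log(totals).mean())
        factors.name = "size_factor"
    normalized = exp.counts.div(factors, axis=1)
    logger.info("size factors: min=%.4g max=%.4g", factors.min(), factors.max())
    return replace(exp, counts=normalized, normalized=True, size_factors=factors)


# ---- imputation ----------------------------------------------------------


def impute_missing_sample(
    exp: TimeCourseExperiment, condition: str, time: float
) -> TimeCourseExperiment:
    """Insert pseudo-samples for missing replicate slots at (condition, time).

    Each pseudo-sample takes the per-gene mean of the surviving replicates at
    the same (condition, time) and is flagged ``imputed``. Pre-existing cells
    are never touched.
    """
    slots = [m for m in exp.missing_pairs() if m[0] == condition and np.isclose(m[1], time)]
    if not slots:
        raise ValueError(f"({condition}, {time}) is not registered as missing")
    survivors = exp.sample_ids(condition, time)
    if not survivors:
        raise ImputationError(f"no surviving replicate at ({condition}, {time})")
    mean = exp.counts[survivors].mean(axis=1)
    counts = exp.counts.copy()
    meta = exp.samples.copy()
    for cond, t, rep in slots:
        sid = f"{cond}_r{rep}_t{t:g}_imputed"
        counts[sid] = mean
        meta.loc[sid] = {"condition": cond, "time_hpf": t, "replicate": rep, "imputed": True}
    return replace(exp, counts=counts, samples=meta)


def impute_all_missing(exp: TimeCourseExperiment) -> TimeCourseExperiment:
    """Impute every missing replicate slot on the grid."""
    pairs = {(c, t) for c, t, _ in exp.missing_pairs()}
    for cond, t in sorted(pairs):
        exp = impute_missing_sample(exp, cond, t)
    return exp


# ---- expression filter ---------------------------------------------------


def filter_threshold(exp: TimeCourseExperiment, threshold: float) -> TimeCourseExperiment:
    """Keep genes whose maximum over all samples reaches ``threshold``.

    The transcript is included if the expression value in at least one data
    point — any condition, any time — is ≥ threshold.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    keep = exp.counts.max(axis=1) >= threshold
    logger.info(
        "expression filter at %g: kept %d genes, removed %d",
        threshold,
        int(keep.sum()),
        int((~keep).sum()),
    )
    return replace(exp, counts=exp.counts.loc[keep])
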
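"""Step 1: per-gene switch-time detection by likelihood-ratio step fitting.

For each gene the time profile (all replicates as individual points) is fit
by a constant model (one mean) and, at every candidate split time, by a
one-step model (one mean before the split, another at and after it). Both
models share a single pooled maximum-likelihood Gaussian variance; the step
model adds exactly one mean parameter, so twice the log-likelihood gain is
referred to a chi-square with one degree of freedom.

A switch is called when the minimum p over candidate splits, adjusted for
the number of splits tried (Bonferroni by default), falls below
``pval_switch``; the switch time is the best-fitting split (ties broken to
the earliest). The sign of the mean difference gives the direction:
"up" profiles are read as zygotic transcription exceeding maternal decay,
"down" profiles as net maternal degradation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .config import AnalysisParams
from .experiment import TimeCourseExperiment

__all__ = [
    "SwitchCall",
    "loglik_constant",
    "loglik_step",
    "lrt_step",
    "detect_switch",
    "switch_scan",
]

#: variance floor for degenerate (zero-spread) profiles
VAR_FLOOR = 1e-8
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class SwitchCall:
    """Outcome of switch detection for one gene."""

    gene: str
    switch_time: float | None
    direction: str  # "up" | "down" | "none"
    pvalue: float  # adjusted minimum p over candidate splits
    mean_before: float
    mean_after: float
    per_time_pvalues: dict[float, float]
    degenerate: bool = False


def _gaussian_ll(n: int, sse: float, var_floor: float) -> tuple[float, bool]:
    var = sse / n
    degenerate = var < var_floor
    if degenerate:
        var = var_floor
    return -0.5 * (n * (_LOG_2PI + np.log(var)) + sse / var), degenerate


def loglik_constant(values: np.ndarray, var_floor: float = VAR_FLOOR) -> tuple[float, bool]:
    """Gaussian log-likelihood of the constant model at its MLE.

    Mean = sample mean, variance = MLE variance over all points, floored at
    ``var_floor`` for zero-spread profiles (degenerate flag returned).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("constant model needs at least 2 values")
    sse = float(((values - values.mean()) ** 2).sum())
    return _gaussian_ll(values.size, sse, var_floor)


def loglik_step(
    values: np.ndarray,
    times: np.ndarray,
    split_time: float,
    var_floor: float = VAR_FLOOR,
) -> tuple[float, float, float, bool]:
    """One-step model: separate means before / at-and-after ``split_time``.

    Returns (log-likelihood, mean_before, mean_after, degenerate). The
    variance is a single pooled MLE across both sides.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    before = values[times < split_time]
    after = values[times >= split_time]
    if before.size == 0 or after.size == 0:
        raise ValueError(f"split at {split_time} leaves an empty side")
    sse = float(((before - before.mean()) ** 2).sum() + ((after - after.mean()) ** 2).sum())
    ll, degenerate = _gaussian_ll(values.size, sse, var_floor)
    return ll, float(before.mean()), float(after.mean()), degenerate


def lrt_step(values: np.ndarray, times: np.ndarray, split_time: float) -> float:
    """LRT p-value of the one-step model against the constant model.

    Statistic = 2·(ℓ_step − ℓ_const), floored at 0, upper chi-square(1) tail.
    When both models hit the variance floor (all-constant profiles) the
    models are indistinguishable and p = 1.
    """
    ll0, deg0 = loglik_constant(values)
    ll1, _, _, deg1 = loglik_step(values, times, split_time)
    if deg0 and deg1:
        return 1.0
    stat = max(0.0, 2.0 * (ll1 - ll0))
    return float(chi2.sf(stat, df=1))


def detect_switch(
    values: np.ndarray,
    times: np.ndarray,
    params: AnalysisParams,
    gene: str = "gene",
    split_correction: str = "bonferroni",
    rule: str = "min_p",
) -> SwitchCall:
    """Scan all candidate split times of one gene and call a switch.

    Candidate splits are every measured time except the earliest (both sides
    of the step must be populated); replicates enter as individual points.
    ``split_correction`` "bonferroni" (default) multiplies the minimum
    per-split p by the number of splits so ``pval_switch`` bounds the
    per-gene false-call rate; "none" compares raw per-split p-values.
    ``rule`` "min_p" (default) places the switch at the best-fitting split,
    earliest on ties; "earliest" takes the first split with raw
    p < pval_switch.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    unique_times = np.unique(times)
    if unique_times.size < 2:
        raise ValueError(f"{gene}: need at least 2 distinct time points")
    if split_correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown split_correction {split_correction!r}")
    if rule not in ("min_p", "earliest"):
        raise ValueError(f"unknown rule {rule!r}")

    splits = unique_times[1:]
    ll0, deg0 = loglik_constant(values)
    pvals = np.empty(splits.size)
    means = np.empty((splits.size, 2))
    any_step_nondeg = False
    for i, s in enumerate(splits):
        ll1, mb, ma, deg1 = loglik_step(values, times, s)
        means[i] = (mb, ma)
        if deg0 and deg1:
            pvals[i] = 1.0
        else:
            any_step_nondeg = True
            pvals[i] = chi2.sf(max(0.0, 2.0 * (ll1 - ll0)), df=1)
    degenerate = deg0 and not any_step_nondeg

    m = splits.size
    pmin = float(pvals.min())
    adjusted = min(1.0, pmin * m) if split_correction == "bonferroni" else pmin
    per_time = {float(t): float(p) for t, p in zip(splits, pvals)}

    chosen: int | None = None
    if adjusted < params.pval_switch:
        if rule == "min_p":
            chosen = int(np.argmin(pvals))  # argmin takes the earliest on ties
        else:
            sig = np.flatnonzero(pvals < params.pval_switch)
            chosen = int(sig[0]) if sig.size else None

    if chosen is None:
        return SwitchCall(
            gene=gene,
            switch_time=None,
            direction="none",
            pvalue=adjusted,
            mean_before=float("nan"),
            mean_after=float("nan"),
            per_time_pvalues=per_time,
            degenerate=degenerate,
        )
    mb, ma = means[chosen]
    direction = "up" if ma > mb else ("down" if ma < mb else "none")
    return SwitchCall(
        gene=gene,
        switch_time=float(splits[chosen]),
        direction=direction,
        pvalue=adjusted,
        mean_before=float(mb),
        mean_after=float(ma),
        per_time_pvalues=per_time,
        degenerate=degenerate,
    )


def switch_scan(
    exp: TimeCourseExperiment,
    condition: str,
    params: AnalysisParams,
    log_transform: bool = False,
    include_imputed: bool = True,
    split_correction: str = "bonferroni",
    rule: str = "min_p",
) -> pd.DataFrame:
    """Run switch detection for every gene of one condition.

    Imputed pseudo-samples participate by default (they restore the time
    grid). ``log_transform`` applies log1p to the normalized counts before
    fitting. Returns a gene-indexed frame with columns switch_time,
    direction, pvalue, mean_before, mean_after, degenerate and one raw
    per-split p column per candidate time (``p_<time>``).
    """
    if condition not in exp.conditions:
        raise ValueError(f"condition {condition!r} not in experiment")
    ids = exp.sample_ids(condition, include_imputed=include_imputed)
    times = exp.samples.loc[ids, "time_hpf"].to_numpy(dtype=float)
    matrix = exp.counts[ids].to_numpy(dtype=float)
    if log_transform:
        matrix = np.log1p(matrix)
    rows = []
    for gene, vals in zip(exp.genes, matrix):
        call = detect_switch(
            vals, times, params, gene=gene, split_correction=split_correction, rule=rule
        )
        row = {
            "switch_time": np.nan if call.switch_time is None else call.switch_time,
            "direction": call.direction,
            "pvalue": call.pvalue,
            "mean_before": call.mean_before,
            "mean_after": call.mean_after,
            "degenerate": call.degenerate,
        }
        row.update({f"p_{t:g}": p for t, p in call.per_time_pvalues.items()})
        rows.append(row)
    base_cols = ["switch_time", "direction", "pvalue", "mean_before", "mean_after", "degenerate"]
    out = pd.DataFrame(rows, index=exp.genes, columns=None if rows else base_cols)
    out.index.name = "gene"
    return out
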
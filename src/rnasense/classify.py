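"""Maternal/zygotic assignment, mutant regulation status, pattern groups.

Switch-UP transcripts in the reference condition are read as zygotic
(zygotic synthesis outpaces maternal decay); switch-DOWN transcripts as
maternal. A zygotic transcript counts as downregulated in a mutant when at
least one significant down fold-change call falls at or after its switch-UP
time; a maternal transcript counts as upregulated when a significant up call
falls after its switch-DOWN time (strictly after by default, mirroring the
differing phrasings of the two rules; both boundaries are flag-switchable).

The three per-mutant down flags of a zygotic gene map onto eight pattern
groups A–H (A: down in all three genotypes ... H: down in none).
Mutant-upregulated transcripts are collected per genotype by re-running
switch detection on each mutant's own profile and requiring a ≥ fc-fold
excess over the reference at one or more time points from the switch on;
transcripts flagged in several genotypes go to the genotype with the highest
maximal expression over its time curve, giving three non-overlapping groups
(I/J/K).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisParams
from .experiment import TimeCourseExperiment
from .switch import switch_scan

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GROUP_LETTERS",
    "DEFAULT_UP_LABELS",
    "assign_class",
    "zygotic_down_status",
    "maternal_up_status",
    "group_zygotic",
    "regulation_table",
    "upregulated_in_mutants",
]

#: (down in MZsox19b, down in MZspg, down in double) → group letter.
#: A, B, D, F and H are anchored by the published group definitions; the
#: letters for the remaining single-mutant-only and double-only patterns
#: (C, E, G) follow the completion of those anchors and can be remapped.
DEFAULT_GROUP_LETTERS: dict[tuple[bool, bool, bool], str] = {
    (True, True, True): "A",
    (True, True, False): "B",
    (True, False, False): "C",
    (True, False, True): "D",
    (False, True, False): "E",
    (False, True, True): "F",
    (False, False, True): "G",
    (False, False, False): "H",
}

#: genotype → upregulated-group label (heatmap ordering: double, MZspg, MZsox19b)
DEFAULT_UP_LABELS: dict[str, str] = {
    "MZsox19bspg": "I",
    "MZspg": "J",
    "MZsox19b": "K",
}

#: deterministic tie-break priority when maximal expression ties exactly
DEFAULT_PRIORITY: tuple[str, ...] = ("MZsox19bspg", "MZspg", "MZsox19b")


def assign_class(switches: pd.DataFrame) -> pd.Series:
    """Map reference-condition switch directions to transcript classes."""
    mapping = {"up": "zygotic", "down": "maternal", "none": "none"}
    cls = switches["direction"].map(mapping)
    if cls.isna().any():
        bad = switches["direction"][cls.isna()].unique().tolist()
        raise ValueError(f"unknown switch direction(s): {bad}")
    return cls.rename("cls")


def _status_from_calls(
    switch_time: float,
    gene_fcs: pd.DataFrame,
    direction: str,
    inclusive: bool,
) -> bool:
    sig = gene_fcs[(gene_fcs["significant"]) & (gene_fcs["direction"] == direction)]
    if inclusive:
        return bool((sig["time_hpf"] >= switch_time).any())
    return bool((sig["time_hpf"] > switch_time).any())


def zygotic_down_status(
    switch_time: float, gene_fcs: pd.DataFrame, inclusive: bool = True
) -> str:
    """"down" iff ≥ 1 significant down call at (or, strict mode, after) the
    switch-UP time; else "unchanged"."""
    return "down" if _status_from_calls(switch_time, gene_fcs, "down", inclusive) else "unchanged"


def maternal_up_status(
    switch_time: float, gene_fcs: pd.DataFrame, strict: bool = True
) -> str:
    """"up" iff ≥ 1 significant up call after the switch-DOWN time (strictly
    after by default); else "unchanged"."""
    return "up" if _status_from_calls(switch_time, gene_fcs, "up", not strict) else "unchanged"


def group_zygotic(
    down_sox19b: bool,
    down_spg: bool,
    down_double: bool,
    letters: dict[tuple[bool, bool, bool], str] | None = None,
) -> str:
    """Map the three per-mutant down flags of a zygotic gene to its group letter."""
    letters = letters if letters is not None else DEFAULT_GROUP_LETTERS
    return letters[(bool(down_sox19b), bool(down_spg), bool(down_double))]


def regulation_table(
    switches_ref: pd.DataFrame,
    fcs_by_mutant: dict[str, pd.DataFrame],
    mutant_order: tuple[str, str, str] = ("MZsox19b", "MZspg", "MZsox19bspg"),
    letters: dict[tuple[bool, bool, bool], str] | None = None,
    maternal_strict_after: bool = True,
    zygotic_inclusive: bool = True,
) -> pd.DataFrame:
    """Per-gene class, per-mutant status, and A–H group for zygotic genes.

    ``fcs_by_mutant`` maps each mutant label to its step-2 frame computed at
    the regulation-status cutoffs (canonically fc = 2, pval_fc = 0.05).
    Maternal genes get up/unchanged statuses and no letter group.
    """
    missing = [m for m in mutant_order if m not in fcs_by_mutant]
    if missing:
        raise ValueError(f"fold-change calls missing for mutants: {missing}")
    cls = assign_class(switches_ref)
    by_gene = {m: dict(tuple(f.groupby("gene"))) for m, f in fcs_by_mutant.items()}
    empty = pd.DataFrame(columns=["time_hpf", "direction", "significant"])

    rows = []
    for gene in switches_ref.index:
        c = cls.loc[gene]
        st = switches_ref.loc[gene, "switch_time"]
        row: dict[str, object] = {"gene": gene, "cls": c, "switch_time": st}
        group = "none"
        statuses = []
        for m in mutant_order:
            gene_fcs = by_gene[m].get(gene, empty)
            if c == "zygotic":
                status = zygotic_down_status(st, gene_fcs, inclusive=zygotic_inclusive)
            elif c == "maternal":
                status = maternal_up_status(st, gene_fcs, strict=maternal_strict_after)
            else:
                status = "unchanged"
            statuses.append(status)
            row[f"status_{m}"] = status
        if c == "zygotic":
            group = group_zygotic(*(s == "down" for s in statuses), letters=letters)
        row["group"] = group
        rows.append(row)
    columns = ["gene", "cls", "switch_time"] + [f"status_{m}" for m in mutant_order] + ["group"]
    out = pd.DataFrame(rows, columns=columns if not rows else None).set_index("gene")
    return out


def upregulated_in_mutants(
    exp: TimeCourseExperiment,
    params: AnalysisParams,
    reference: str = "WT",
    mutants: tuple[str, ...] = ("MZsox19bspg", "MZspg", "MZsox19b"),
    labels: dict[str, str] | None = None,
    inclusive_after: bool = True,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    pseudocount: float = 1.0,
    split_correction: str = "bonferroni",
) -> pd.DataFrame:
    """Transcripts zygotically upregulated in the mutants, grouped by genotype.

    Per mutant, switch detection (same parameters as the reference run) is
    re-run on the mutant's own profile; a transcript qualifies when it (1)
    switches UP in that mutant and (2) exceeds the reference ≥ fc-fold at one
    or more time points from the switch on (replicate means,
    pseudocount-protected). Transcripts qualifying in several genotypes are
    assigned to the genotype whose time curve reaches the highest maximal
    expression; exact ties fall back to a fixed genotype priority and are
    logged. Returns a frame (gene, genotype, group, max_expression) with
    non-overlapping genotype groups.
    """
    labels = labels if labels is not None else DEFAULT_UP_LABELS
    cond_means = {
        cond: exp.values(condition=cond)
        .T.groupby(exp.samples.loc[exp.sample_ids(cond), "time_hpf"].to_numpy())
        .mean()
        .T
        for cond in (reference, *mutants)
    }
    ref_means = cond_means[reference]

    flagged: dict[str, list[str]] = {}
    for mut in mutants:
        sw = switch_scan(exp, mut, params, split_correction=split_correction)
        up = sw[sw["direction"] == "up"]
        mut_means = cond_means[mut]
        times = ref_means.columns.to_numpy(dtype=float)
        for gene, rec in up.iterrows():
            t0 = rec["switch_time"]
            sel = times >= t0 if inclusive_after else times > t0
            ratio = (mut_means.loc[gene, sel] + pseudocount) / (
                ref_means.loc[gene, sel] + pseudocount
            )
            if (ratio >= params.fc).any():
                flagged.setdefault(gene, []).append(mut)

    rows = []
    for gene, muts in flagged.items():
        if len(muts) == 1:
            chosen = muts[0]
        else:
            peaks = {m: float(cond_means[m].loc[gene].max()) for m in muts}
            best = max(peaks.values())
            top = [m for m in muts if peaks[m] == best]
            if len(top) > 1:
                top.sort(key=priority.index)
                logger.info("tie on max expression for %s; assigned to %s", gene, top[0])
            chosen = top[0]
        rows.append(
            {
                "gene": gene,
                "genotype": chosen,
                "group": labels.get(chosen, chosen),
                "max_expression": float(cond_means[chosen].loc[gene].max()),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "genotype", "group", "max_expression"])
    return out.sort_values(["group", "gene"]).reset_index(drop=True)
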
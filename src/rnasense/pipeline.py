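"""End-to-end run: normalize → impute → filter → switch → fold change →
matrix + Fisher → classify, with a reproducibility manifest.

All tabular outputs are TSV with a fixed float format, so a rerun on
identical inputs and configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import regulation_table, upregulated_in_mutants
from .combine import build_matrix, fisher_matrix
from .config import AnalysisParams, RunConfig
from .experiment import (
    filter_threshold,
    impute_all_missing,
    normalize_sizefactors,
    read_experiment,
)
from .foldchange import apply_cutoffs, fc_scan
from .switch import switch_scan

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

_FLOAT_FMT = "%.10g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path, index_label: str | None = "gene") -> None:
    frame.to_csv(
        path,
        sep="\t",
        float_format=_FLOAT_FMT,
        na_rep="NA",
        index=index_label is not None,
        index_label=index_label,
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis described by ``config``; returns output paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params
    outputs: dict[str, Path] = {}

    exp = read_experiment(config.counts, config.metadata)
    exp = normalize_sizefactors(exp)
    outputs["size_factors"] = outdir / "size_factors.tsv"
    exp.size_factors.to_frame().to_csv(
        outputs["size_factors"], sep="\t", float_format=_FLOAT_FMT, index_label="sample"
    )
    exp = impute_all_missing(exp)
    exp = filter_threshold(exp, params.threshold)

    if exp.n_genes == 0:
        logger.warning("no gene passes the expression threshold %g; writing empty outputs", params.threshold)

    # step 1 on the reference condition
    switches = switch_scan(
        exp,
        params.condition_step_detection,
        params,
        log_transform=config.log_transform,
        split_correction=config.split_correction,
        rule=config.switch_rule,
    )
    outputs["switch"] = outdir / f"switch_{params.condition_step_detection}.tsv"
    _write(switches, outputs["switch"])

    # step 2 per mutant (cutoff-free p-values; both cutoffs derived from one scan)
    status_params = AnalysisParams(
        pval_switch=params.pval_switch,
        pval_fc=config.pval_fc_status,
        fc=params.fc,
        threshold=params.threshold,
        condition_step_detection=params.condition_step_detection,
    )
    fcs_matrix: dict[str, pd.DataFrame] = {}
    fcs_status: dict[str, pd.DataFrame] = {}
    for mut in config.alternates:
        fc = fc_scan(exp, config.reference, mut, params) if exp.n_genes else _empty_fc()
        fcs_matrix[mut] = fc
        fcs_status[mut] = apply_cutoffs(fc, status_params) if exp.n_genes else fc
        outputs[f"fc_{mut}"] = outdir / f"fc_{mut}.tsv"
        _write(fc, outputs[f"fc_{mut}"], index_label=None)

        matrix = build_matrix(switches, fc, include_none_switch=config.include_none_switch)
        tiles = fisher_matrix(matrix)
        outputs[f"matrix_{mut}"] = outdir / f"switchfc_matrix_{mut}.tsv"
        _write(tiles, outputs[f"matrix_{mut}"], index_label=None)

    # classification at the status cutoffs
    mutant_order = tuple(config.alternates)
    if len(mutant_order) == 3:
        table = regulation_table(
            switches,
            fcs_status,
            mutant_order=mutant_order,
            maternal_strict_after=config.maternal_strict_after,
            zygotic_inclusive=True,
        )
        outputs["regulation"] = outdir / "regulation_table.tsv"
        _write(table, outputs["regulation"])

        up = (
            upregulated_in_mutants(
                exp,
                params,
                reference=config.reference,
                mutants=mutant_order[::-1],
                inclusive_after=config.mutant_up_inclusive,
                split_correction=config.split_correction,
            )
            if exp.n_genes
            else pd.DataFrame(columns=["gene", "genotype", "group", "max_expression"])
        )
        outputs["upregulated"] = outdir / "upregulated_groups.tsv"
        _write(up, outputs["upregulated"], index_label=None)
    else:
        logger.warning(
            "pattern-group classification needs exactly 3 mutant conditions; got %d",
            len(mutant_order),
        )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "params": dataclasses.asdict(params),
        "pval_fc_status": config.pval_fc_status,
        "reference": config.reference,
        "alternates": list(config.alternates),
        "flags": {
            "log_transform": config.log_transform,
            "maternal_strict_after": config.maternal_strict_after,
            "mutant_up_inclusive": config.mutant_up_inclusive,
            "include_none_switch": config.include_none_switch,
            "split_correction": config.split_correction,
            "switch_rule": config.switch_rule,
        },
        "inputs": {
            "counts": {"path": str(config.counts), "sha256": _sha256(Path(config.counts))},
            "metadata": {"path": str(config.metadata), "sha256": _sha256(Path(config.metadata))},
        },
        "n_genes_analyzed": int(exp.n_genes),
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    return outputs


def _empty_fc() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene", "time_hpf", "pvalue", "log2fc", "direction", "significant"]
    )
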
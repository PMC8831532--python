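"""Analysis parameters and run configuration.

The defaults reproduce the canonical parameterization of the three-step
time-course analysis: a liberal switch cutoff (pval_switch = 0.15), a strict
per-time-point fold-change cutoff (pval_fc = 0.01) with a 2-fold linear
threshold, and an expression floor of 100 normalized counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["AnalysisParams", "RunConfig"]


@dataclass(frozen=True)
class AnalysisParams:
    """User-facing cutoffs of the three-step analysis.

    Parameters
    ----------
    pval_switch
        p-value cutoff for switch detection (step 1). Applied to the
        multiplicity-adjusted minimum LRT p over candidate split times, so it
        bounds the per-gene false-call rate.
    pval_fc
        p-value cutoff for the per-time-point exact NB test (step 2).
    fc
        Linear fold-change cutoff for step 2 (``fc=1`` disables it).
    threshold
        Minimum expression (normalized counts) a gene must reach in at least
        one sample to enter the analysis.
    condition_step_detection
        Condition label whose time profile is used for switch detection.
    """

    pval_switch: float = 0.15
    pval_fc: float = 0.01
    fc: float = 2.0
    threshold: float = 100.0
    condition_step_detection: str = "WT"

    def __post_init__(self) -> None:
        if not (0.0 < self.pval_switch <= 1.0):
            raise ValueError(f"pval_switch must be in (0, 1], got {self.pval_switch}")
        if not (0.0 < self.pval_fc <= 1.0):
            raise ValueError(f"pval_fc must be in (0, 1], got {self.pval_fc}")
        if self.fc < 1.0:
            raise ValueError(f"fc must be >= 1, got {self.fc}")
        if self.threshold < 0.0:
            raise ValueError(f"threshold must be >= 0, got {self.threshold}")


@dataclass
class RunConfig:
    """Full configuration of a pipeline run; round-trips through YAML."""

    counts: str = "counts.tsv"
    metadata: str = "metadata.tsv"
    outdir: str = "rnasense_out"
    params: AnalysisParams = field(default_factory=AnalysisParams)
    reference: str = "WT"
    alternates: Sequence[str] = ("MZsox19b", "MZspg", "MZsox19bspg")
    #: step-2 cutoff used for the regulation-status assignment (the matrix run
    #: uses ``params.pval_fc``); the two runs share p-values, only the cutoff
    #: differs.
    pval_fc_status: float = 0.05
    log_transform: bool = False
    #: maternal "upregulated after the switch DOWN": strictly after if True
    maternal_strict_after: bool = True
    #: mutant-upregulation "after the switch UP": at-or-after if True
    mutant_up_inclusive: bool = True
    include_none_switch: bool = False
    split_correction: str = "bonferroni"
    switch_rule: str = "min_p"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.params, dict):
            self.params = AnalysisParams(**self.params)
        self.alternates = tuple(self.alternates)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alternates"] = list(self.alternates)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls(**data)
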
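"""Seeded generator of ground-truth-labeled time-course count data.

The generator emulates the study design the analysis targets: eight time
points from 2.5 to 6 hpf at 30-minute spacing, four wild-type replicates and
two per mutant genotype, and three expression archetypes — flat profiles,
maternal decay (exponential halving per grid step after a switch-DOWN time)
and zygotic step-up (a step of fixed amplitude at the switch-UP time).
Genotype effects are scripted per gene: down-scaling of the post-switch
zygotic level, delay of the maternal decay (read downstream as mutant
upregulation) and ectopic activation of a flat transcript in one mutant.
Counts are negative-binomial with gene-wise dispersion (variance μ + φμ²)
around the scripted means scaled by per-sample library factors, and one
replicate slot can be deliberately removed to exercise imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiment import TimeCourseExperiment, write_experiment

__all__ = [
    "SyntheticSpec",
    "apply_delay",
    "apply_scale_after",
    "apply_ectopic",
    "make_profiles",
    "sample_counts",
    "simulate",
    "write_truth",
]

DEFAULT_TIMES = tuple(np.arange(2.5, 6.01, 0.5))
MUTANTS = ("MZsox19b", "MZspg", "MZsox19bspg")

#: zygotic pattern-group proportions used to script mutant down-effects;
#: loosely shaped like the published composition (large H, A biggest among
#: the affected groups) without claiming its exact fractions
DEFAULT_GROUP_PROBS: dict[str, float] = {
    "A": 0.17,
    "B": 0.08,
    "C": 0.05,
    "D": 0.06,
    "E": 0.05,
    "F": 0.06,
    "G": 0.13,
    "H": 0.40,
}

#: group letter → mutants with a scripted down-effect
GROUP_DOWN_MUTANTS: dict[str, tuple[str, ...]] = {
    "A": ("MZsox19b", "MZspg", "MZsox19bspg"),
    "B": ("MZsox19b", "MZspg"),
    "C": ("MZsox19b",),
    "D": ("MZsox19b", "MZsox19bspg"),
    "E": ("MZspg",),
    "F": ("MZspg", "MZsox19bspg"),
    "G": ("MZsox19bspg",),
    "H": (),
}


@dataclass
class SyntheticSpec:
    """Study conditions of one synthetic experiment.

    Means are on the normalized-count scale (the analysis threshold of 100
    sits between the zygotic pre-switch baseline and the expressed levels).
    """

    n_flat: int = 600
    n_zygotic: int = 200
    n_maternal: int = 200
    times: tuple[float, ...] = DEFAULT_TIMES
    replicates: dict[str, int] = field(
        default_factory=lambda: {"WT": 4, "MZsox19b": 2, "MZspg": 2, "MZsox19bspg": 2}
    )
    reference: str = "WT"
    baseline: float = 50.0  # zygotic pre-switch level
    flat_level: float = 300.0
    maternal_level: float = 400.0
    amplitude: float = 8.0  # zygotic step, fold over baseline
    dispersion: float = 0.05
    switch_window: tuple[float, float] = (3.5, 5.0)  # true switch times on the grid
    group_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_PROBS))
    down_effect: float = 0.25  # post-switch scaling in affected mutants (4-fold down)
    maternal_up_fraction: float = 0.25  # chance a maternal gene is delayed per mutant
    maternal_up_delay: int = 2  # grid steps of decay delay in affected mutants
    ectopic_fraction: float = 0.05  # fraction of flat genes ectopically activated
    ectopic_amplitude: float = 8.0
    ectopic_window: tuple[float, float] = (4.5, 5.5)
    libsize_sigma: float = 0.15  # log-normal spread of per-sample library factors
    missing: tuple[tuple[str, float, int], ...] = (("MZsox19bspg", 6.0, 2),)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_flat, self.n_zygotic, self.n_maternal) < 0:
            raise ValueError("gene counts must be non-negative")
        if self.amplitude < 1 or self.ectopic_amplitude < 1:
            raise ValueError("step amplitudes must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        self.times = tuple(float(t) for t in self.times)
        self.missing = tuple((c, float(t), int(r)) for c, t, r in self.missing)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["times"] = list(self.times)
        d["switch_window"] = list(self.switch_window)
        d["ectopic_window"] = list(self.ectopic_window)
        d["missing"] = [list(m) for m in self.missing]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"spec file {path} does not contain a mapping")
        for key in ("switch_window", "ectopic_window"):
            if key in data:
                data[key] = tuple(data[key])
        if "missing" in data:
            data["missing"] = tuple(tuple(m) for m in data["missing"])
        return cls(**data)


# ---- effect scripts ------------------------------------------------------


def apply_delay(curve: np.ndarray, steps: int) -> np.ndarray:
    """Shift a mean curve right by ``steps`` grid positions, holding the
    initial value."""
    if steps <= 0:
        return curve.copy()
    out = np.empty_like(curve)
    out[:steps] = curve[0]
    out[steps:] = curve[: curve.size - steps]
    return out


def apply_scale_after(
    curve: np.ndarray, times: np.ndarray, t0: float, factor: float
) -> np.ndarray:
    """Scale the curve by ``factor`` at and after time ``t0``."""
    out = curve.copy()
    out[times >= t0] *= factor
    return out


def apply_ectopic(
    curve: np.ndarray, times: np.ndarray, t0: float, amplitude: float
) -> np.ndarray:
    """Step the curve up ``amplitude``-fold at and after time ``t0``."""
    out = curve.copy()
    out[times >= t0] *= amplitude
    return out


# ---- mean curves ---------------------------------------------------------


def _grid_choice(rng: np.random.Generator, times: np.ndarray, window: tuple[float, float], size: int) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    candidates = times[(times >= window[0]) & (times <= window[1])]
    if candidates.size == 0:
        raise ValueError(f"no grid time inside window {window}")
    return rng.choice(candidates, size=size)


def make_profiles(spec: SyntheticSpec) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-condition mean curves (genes × times) plus the truth table.

    Truth columns: archetype, true_switch (reference-condition switch time;
    NaN for flat genes), true_class, true_group (A–H letter for zygotic,
    genotype label for ectopically activated flat genes, else "none") and one
    true_status_<mutant> column per mutant (down/up/unchanged).
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.times, dtype=float)
    conditions = list(spec.replicates)
    mutants = [c for c in conditions if c != spec.reference]

    genes: list[str] = []
    wt_curves: list[np.ndarray] = []
    truth_rows: list[dict] = []
    mutant_overrides: dict[str, dict[int, np.ndarray]] = {m: {} for m in mutants}

    # flat genes, a few with scripted ectopic activation in one mutant
    n_ectopic = int(round(spec.ectopic_fraction * spec.n_flat))
    ectopic_idx = set(rng.choice(spec.n_flat, size=n_ectopic, replace=False)) if n_ectopic else set()
    ectopic_mutants = rng.choice(mutants, size=n_ectopic) if n_ectopic else []
    ectopic_times = _grid_choice(rng, times, spec.ectopic_window, n_ectopic) if n_ectopic else []
    ect_j = 0
    for i in range(spec.n_flat):
        gid = f"flat_{i:04d}"
        curve = np.full(times.size, spec.flat_level)
        row = {
            "gene": gid,
            "archetype": "flat",
            "true_switch": np.nan,
            "true_class": "none",
            "true_group": "none",
            **{f"true_status_{m}": "unchanged" for m in mutants},
        }
        if i in ectopic_idx:
            mut = str(ectopic_mutants[ect_j])
            t0 = float(ectopic_times[ect_j])
            ect_j += 1
            mutant_overrides[mut][len(genes)] = apply_ectopic(
                curve, times, t0, spec.ectopic_amplitude
            )
            row["true_group"] = mut
            row[f"true_status_{mut}"] = "up"
        genes.append(gid)
        wt_curves.append(curve)
        truth_rows.append(row)

    # zygotic step genes with scripted per-group mutant down-effects
    letters = list(spec.group_probs)
    probs = np.array([spec.group_probs[g] for g in letters], dtype=float)
    probs = probs / probs.sum()
    zyg_groups = rng.choice(letters, size=spec.n_zygotic, p=probs)
    zyg_switch = _grid_choice(rng, times, spec.switch_window, spec.n_zygotic)
    for i in range(spec.n_zygotic):
        gid = f"zyg_{i:04d}"
        t0 = float(zyg_switch[i])
        group = str(zyg_groups[i])
        curve = np.where(times >= t0, spec.baseline * spec.amplitude, spec.baseline)
        row = {
            "gene": gid,
            "archetype": "zygotic_step",
            "true_switch": t0,
            "true_class": "zygotic",
            "true_group": group,
            **{f"true_status_{m}": "unchanged" for m in mutants},
        }
        for mut in GROUP_DOWN_MUTANTS.get(group, ()):
            if mut in mutant_overrides:
                mutant_overrides[mut][len(genes)] = apply_scale_after(
                    curve, times, t0, spec.down_effect
                )
                row[f"true_status_{mut}"] = "down"
        genes.append(gid)
        wt_curves.append(curve)
        truth_rows.append(row)

    # maternal decay genes; delayed decay in affected mutants reads as "up"
    mat_switch = _grid_choice(rng, times, spec.switch_window, spec.n_maternal)
    mat_up = rng.random((spec.n_maternal, len(mutants))) < spec.maternal_up_fraction
    step = float(times[1] - times[0]) if times.size > 1 else 1.0
    for i in range(spec.n_maternal):
        gid = f"mat_{i:04d}"
        t0 = float(mat_switch[i])
        curve = spec.maternal_level * 0.5 ** np.maximum(0.0, (times - t0) / step)
        row = {
            "gene": gid,
            "archetype": "maternal_decay",
            "true_switch": t0,
            "true_class": "maternal",
            "true_group": "none",
            **{f"true_status_{m}": "unchanged" for m in mutants},
        }
        for j, mut in enumerate(mutants):
            if mat_up[i, j]:
                mutant_overrides[mut][len(genes)] = apply_delay(
                    curve, spec.maternal_up_delay
                )
                row[f"true_status_{mut}"] = "up"
        genes.append(gid)
        wt_curves.append(curve)
        truth_rows.append(row)

    wt = np.array(wt_curves) if wt_curves else np.empty((0, times.size))
    profiles = {spec.reference: pd.DataFrame(wt, index=genes, columns=times)}
    for mut in mutants:
        mat = wt.copy()
        for idx, curve in mutant_overrides[mut].items():
            mat[idx] = curve
        profiles[mut] = pd.DataFrame(mat, index=genes, columns=times)
    truth = pd.DataFrame(truth_rows, columns=list(truth_rows[0]) if truth_rows else ["gene"])
    if not truth.empty:
        truth = truth.set_index("gene")
    return profiles, truth


# ---- sampling ------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def sample_counts(
    profiles: dict[str, pd.DataFrame], spec: SyntheticSpec
) -> TimeCourseExperiment:
    """Draw NB counts around the scripted means.

    One sample (column) per (condition, replicate, time); each sample gets a
    log-normal library factor; the slots listed in ``spec.missing`` are
    removed so that downstream imputation has work to do. Output counts are
    raw integers (``normalized=False``).
    """
    rng = np.random.default_rng(spec.seed + 1)
    times = np.asarray(spec.times, dtype=float)
    missing = set(spec.missing)
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for cond, n_rep in spec.replicates.items():
        curves = profiles[cond].to_numpy(dtype=float)
        for rep in range(1, n_rep + 1):
            for j, t in enumerate(times):
                lib = float(rng.lognormal(0.0, spec.libsize_sigma))
                draw = _nb_draw(rng, curves[:, j] * lib, spec.dispersion)
                if (cond, float(t), rep) in missing:
                    continue  # drawn then dropped: keeps the stream aligned
                sid = f"{cond}_r{rep}_t{t:g}"
                columns[sid] = draw
                meta_rows.append(
                    {"sample": sid, "condition": cond, "time_hpf": float(t), "replicate": rep}
                )
    genes = profiles[spec.reference].index
    counts = pd.DataFrame(columns, index=genes, dtype=float)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    counts.index.name = "gene"
    return TimeCourseExperiment(counts=counts, samples=meta)


def simulate(
    spec: SyntheticSpec | None = None, seed: int | None = None
) -> tuple[TimeCourseExperiment, pd.DataFrame]:
    """Generate one experiment plus its truth table (fixed seed ⇒ identical
    output)."""
    spec = spec if spec is not None else SyntheticSpec()
    if seed is not None:
        spec = SyntheticSpec(**{**asdict(spec), "seed": seed})
    profiles, truth = make_profiles(spec)
    exp = sample_counts(profiles, spec)
    return exp, truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", float_format="%.10g", index_label="gene")
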
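"""Step 3: cross-tabulate switch times against fold-change calls.

Every significant per-time-point fold-change call of a switched gene becomes
one event (gene, switch time, fold-change time, direction); a gene with
significant fold changes at k time points contributes k events. Events are
tabulated in a matrix with switch time on the rows and (fold-change time ×
direction) on the columns, and each tile is scored with a one-sided
(enrichment) Fisher exact test over events: a small p marks a tile holding
more events than independence of the two time coordinates would predict,
i.e. a set of genes whose switch is shifted in the mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["SwitchFCMatrix", "build_matrix", "fisher_tile", "fisher_matrix"]

EVENT_COLUMNS = ("gene", "switch_time", "fc_time", "direction")


@dataclass
class SwitchFCMatrix:
    """Event list plus its (switch time × fold-change time × direction) tally."""

    events: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event frame lacks columns {missing}")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def tile_counts(self) -> pd.DataFrame:
        """Long tally: one row per occupied (switch_time, fc_time, direction)."""
        if self.events.empty:
            return pd.DataFrame(columns=["switch_time", "fc_time", "direction", "count"])
        counts = (
            self.events.groupby(["switch_time", "fc_time", "direction"], sort=True)
            .size()
            .rename("count")
            .reset_index()
        )
        return counts


def build_matrix(
    switches: pd.DataFrame,
    fcs: pd.DataFrame,
    include_none_switch: bool = False,
) -> SwitchFCMatrix:
    """Combine step-1 calls with step-2 calls into the event matrix.

    ``switches``: gene-indexed frame with a ``switch_time`` column (NaN for
    no switch). ``fcs``: long frame from :func:`~rnasense.foldchange.fc_scan`.
    Genes without a switch call contribute no events unless
    ``include_none_switch`` adds them under the row label "none".
    """
    sig = fcs[fcs["significant"]]
    switch_time = switches["switch_time"]
    rows = []
    for rec in sig.itertuples(index=False):
        if rec.gene not in switch_time.index:
            continue
        s = switch_time.loc[rec.gene]
        if pd.isna(s):
            if not include_none_switch:
                continue
            s = "none"
        else:
            s = float(s)
        rows.append((rec.gene, s, float(rec.time_hpf), rec.direction))
    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    return SwitchFCMatrix(events=events)


def fisher_tile(
    matrix: SwitchFCMatrix,
    switch_time: float | str,
    fc_time: float,
    direction: str,
) -> float:
    """One-sided enrichment p for one tile.

    Over the N events, the 2×2 table crosses membership in the tile's row
    (switch time) with membership in its column (fold-change time ×
    direction); the p-value is the upper hypergeometric tail P(X ≥ k) at the
    tile's event count k. An empty matrix gives p = 1.
    """
    ev = matrix.events
    n_total = len(ev)
    if n_total == 0:
        return 1.0
    in_row = ev["switch_time"] == switch_time
    in_col = (ev["fc_time"] == fc_time) & (ev["direction"] == direction)
    k_row = int(in_row.sum())
    n_col = int(in_col.sum())
    k = int((in_row & in_col).sum())
    p = float(hypergeom.sf(k - 1, n_total, k_row, n_col))
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def fisher_matrix(matrix: SwitchFCMatrix) -> pd.DataFrame:
    """Tile tally with a Fisher enrichment p per occupied tile (long format)."""
    counts = matrix.tile_counts()
    pvals = [
        fisher_tile(matrix, rec.switch_time, rec.fc_time, rec.direction)
        for rec in counts.itertuples(index=False)
    ]
    out = counts.assign(pvalue=pvals)
    return out
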
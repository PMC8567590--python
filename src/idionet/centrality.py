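"""Node-strength centrality and top-two treatment-target selection.

For the contemporaneous network the statistic is strength (sum of absolute
edge weights attached to a node); for the temporal network it is out-strength
(sum over outgoing edges — the influence a symptom exerts on the next beep)
and in-strength (sum over incoming edges).  Self-loops (the autoregressive
diagonal) are excluded by default: a symptom predicting itself is not an
inter-symptom pathway.

Target rules: the top two items per statistic are proposed as treatment
targets.  If every centrality value is exactly zero the participant has no
identifiable target (NA).  Exact ties at the top put all tied items in rank
1 and leave rank 2 empty; a tie between the second and third values puts
both items in rank 2.  Items with exactly-zero centrality are never listed
as targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gvar import NetworkPair

__all__ = [
    "STATISTICS",
    "CentralityTable",
    "TargetSelection",
    "compute_centrality",
    "select_targets",
]

STATISTICS = ("strength", "out_strength", "in_strength")

#: Two standardized edge weights closer than this are treated as tied.
TIE_TOL = 1e-12


@dataclass
class CentralityTable:
    """Per-item strength statistics for one participant's network pair."""

    items: tuple[str, ...]
    strength: np.ndarray
    out_strength: np.ndarray
    in_strength: np.ndarray

    def values(self, statistic: str) -> np.ndarray:
        if statistic not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}")
        return getattr(self, statistic)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.items,
                "strength": self.strength,
                "out_strength": self.out_strength,
                "in_strength": self.in_strength,
            }
        )


@dataclass
class TargetSelection:
    """Top-two target ranking for one participant and one statistic."""

    participant_id: str
    statistic: str
    rank1: tuple[str, ...]
    rank2: tuple[str, ...]
    is_na: bool
    rank1_tie: bool = False
    tie_note: str = ""
    values: dict[str, float] = field(default_factory=dict)


def compute_centrality(net: NetworkPair, include_self_loops: bool = False) -> CentralityTable:
    """Absolute-value strength sums over the network pair.

    ``net.temporal[i, j]`` is the edge j -> i, so out-strength is a column
    sum and in-strength a row sum.  The diagonal (self-loop) is excluded
    unless ``include_self_loops`` — and never contributes to strength on the
    contemporaneous side, whose diagonal is structurally zero.
    """
    T = np.abs(net.temporal).astype(float)
    C = np.abs(net.contemporaneous).astype(float)
    if not include_self_loops:
        T = T.copy()
        np.fill_diagonal(T, 0.0)
    C = C.copy()
    np.fill_diagonal(C, 0.0)
    return CentralityTable(
        items=net.items,
        strength=C.sum(axis=1),
        out_strength=T.sum(axis=0),
        in_strength=T.sum(axis=1),
    )


def select_targets(
    cent: CentralityTable,
    statistic: str,
    participant_id: str | None = None,
    tie_tol: float = TIE_TOL,
) -> TargetSelection:
    """Apply the top-two rule with tie and NA handling.

    Items are ranked by descending centrality, catalog order breaking the
    presentation order inside tied groups.  ``is_na`` is true exactly when
    every value is zero.  Scaling all values by a positive constant never
    changes the selection (the tie tolerance is absolute on standardized
    weights, where exact ties arise as exact floating-point equalities).
    """
    v = np.asarray(cent.values(statistic), dtype=float)
    pid = participant_id if participant_id is not None else ""
    nonzero = np.flatnonzero(v > 0)
    if nonzero.size == 0:
        return TargetSelection(pid, statistic, (), (), is_na=True,
                               tie_note="no central symptom identified")
    order = nonzero[np.argsort(-v[nonzero], kind="stable")]
    vals = v[order]
    top = vals[0]
    in_rank1 = np.abs(vals - top) <= tie_tol
    rank1_idx = order[in_rank1]
    values = {cent.items[j]: float(v[j]) for j in order}
    if rank1_idx.size > 1:
        return TargetSelection(
            pid, statistic,
            tuple(cent.items[j] for j in rank1_idx), (),
            is_na=False, rank1_tie=True,
            tie_note="tie at rank 1; all tied items listed under rank 1",
            values=values,
        )
    rest = order[~in_rank1]
    if rest.size == 0:
        return TargetSelection(
            pid, statistic, (cent.items[rank1_idx[0]],), (),
            is_na=False, values=values,
            tie_note="only one item with nonzero centrality",
        )
    second = v[rest[0]]
    in_rank2 = np.abs(v[rest] - second) <= tie_tol
    rank2_idx = rest[in_rank2]
    note = "tie at rank 2; all tied items listed under rank 2" if rank2_idx.size > 1 else ""
    return TargetSelection(
        pid, statistic,
        (cent.items[rank1_idx[0]],),
        tuple(cent.items[j] for j in rank2_idx),
        is_na=False, tie_note=note, values=values,
    )
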
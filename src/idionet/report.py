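"""Cohort-level aggregation: target frequency tables and network figures.

The per-participant top-two targets are aggregated into frequency tables,
one per (network kind, item count): contemporaneous tables have columns for
highest and second-highest strength; temporal tables have four columns
(highest/second out-strength, highest/second in-strength) plus an NA row for
participants with no identifiable temporal target in that column.

Accounting rules: every item listed in a rank increments that rank's column
(a rank-1 tie adds one count per tied item, inflating the column total and
leaving the participant absent from the rank-2 column); a participant whose
network yields no target for a column increments the NA row of temporal
tables.  Percentages are column counts over the column total, rounded
half-up to one decimal; the row-total percentage uses the grand total (the
sum of column totals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .centrality import TargetSelection
from .ema import SymptomCatalog
from .gvar import NetworkPair

__all__ = [
    "CohortFrequencyTable",
    "round_half_up",
    "tabulate",
    "summarize_distinct_targets",
    "render_networks",
]

KIND_STATISTICS = {
    "contemporaneous": ("strength",),
    "temporal": ("out_strength", "in_strength"),
}

NA_ROW = "NA"
TOTAL_ROW = "Total"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (so 10.25 -> 10.3), matching printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortFrequencyTable:
    """Counts and percentages of selected targets across a cohort.

    ``counts`` has one row per item that was ever selected (plus an NA row
    for temporal tables) and one column per (statistic, rank); ``table`` is
    the printable version with ``"count (pct)"`` cells, a total column and a
    Total row.
    """

    network_kind: str
    k: int
    n_participants: int
    counts: pd.DataFrame
    column_totals: pd.Series
    grand_total: int

    @property
    def columns(self) -> list[str]:
        return list(self.counts.columns)

    def percentages(self) -> pd.DataFrame:
        pct = self.counts.astype(float).copy()
        for col in pct.columns:
            total = self.column_totals[col]
            pct[col] = [
                round_half_up(100.0 * c / total, 1) if total else 0.0
                for c in self.counts[col]
            ]
        return pct

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def total_percentages(self) -> pd.Series:
        rt = self.row_totals()
        return pd.Series(
            [round_half_up(100.0 * t / self.grand_total, 1) if self.grand_total else 0.0
             for t in rt],
            index=rt.index,
        )

    def formatted(self) -> pd.DataFrame:
        """Printable table: 'count (pct)' cells, total column, Total row."""
        pct = self.percentages()
        out = pd.DataFrame(index=self.counts.index)
        for col in self.counts.columns:
            out[col] = [
                f"{c} ({p:.1f})" for c, p in zip(self.counts[col], pct[col])
            ]
        rt, tp = self.row_totals(), self.total_percentages()
        out["Total"] = [f"{c} ({p:.1f})" for c, p in zip(rt, tp)]
        total_row = {
            col: f"{int(self.column_totals[col])} (100.0)" for col in self.counts.columns
        }
        total_row["Total"] = f"{self.grand_total} (100.0)"
        out.loc[TOTAL_ROW] = total_row
        return out

    def to_csv(self, path: str | Path) -> None:
        self.formatted().rename_axis("item").to_csv(path)

    def to_markdown(self) -> str:
        df = self.formatted().rename_axis("item").reset_index()
        header = "| " + " | ".join(df.columns) + " |"
        sep = "| " + " | ".join("---" for _ in df.columns) + " |"
        rows = ["| " + " | ".join(str(v) for v in rec) + " |" for rec in df.itertuples(index=False)]
        return "\n".join([header, sep, *rows])


def _column_name(statistic: str, rank: int) -> str:
    label = {"strength": "strength", "out_strength": "out-strength",
             "in_strength": "in-strength"}[statistic]
    return f"{'highest' if rank == 1 else 'second-highest'} {label}"


def tabulate(
    selections: list[TargetSelection],
    network_kind: str,
    k: int,
    catalog: SymptomCatalog | None = None,
) -> CohortFrequencyTable:
    """Aggregate per-participant target selections into a frequency table.

    ``selections`` must hold exactly one entry per participant for each
    statistic of ``network_kind``.  NA selections (and rank-2 columns left
    empty because no second nonzero-centrality item existed) increment the
    NA row of temporal tables; a rank-1 tie instead deflates the rank-2
    column.  Rows are ordered by descending total count, then catalog order.
    """
    if network_kind not in KIND_STATISTICS:
        raise ValueError(f"network_kind must be one of {sorted(KIND_STATISTICS)}")
    stats = KIND_STATISTICS[network_kind]
    extra = {s.statistic for s in selections} - set(stats)
    if extra:
        raise ValueError(
            f"selections for {sorted(extra)} do not belong in a {network_kind} table"
        )
    by_stat: dict[str, list[TargetSelection]] = {s: [] for s in stats}
    for sel in selections:
        by_stat[sel.statistic].append(sel)
    n_participants = {s: len(v) for s, v in by_stat.items()}
    if len(set(n_participants.values())) != 1:
        raise ValueError(f"unbalanced selections per statistic: {n_participants}")
    n = next(iter(n_participants.values()))
    for s, sels in by_stat.items():
        pids = [x.participant_id for x in sels]
        if len(set(pids)) != len(pids):
            raise ValueError(f"duplicate participant in {s} selections")

    has_na_row = network_kind == "temporal"
    columns = [(s, r) for s in stats for r in (1, 2)]
    counts: dict[tuple[str, int], dict[str, int]] = {c: {} for c in columns}
    na_counts = {c: 0 for c in columns}
    for s, sels in by_stat.items():
        for sel in sels:
            # rank-1 column
            if sel.is_na:
                na_counts[(s, 1)] += 1
            else:
                for item in sel.rank1:
                    counts[(s, 1)][item] = counts[(s, 1)].get(item, 0) + 1
            # rank-2 column
            if sel.is_na:
                na_counts[(s, 2)] += 1
            elif sel.rank2:
                for item in sel.rank2:
                    counts[(s, 2)][item] = counts[(s, 2)].get(item, 0) + 1
            elif not sel.rank1_tie:
                # no second nonzero-centrality item: absent target
                na_counts[(s, 2)] += 1

    items = sorted({i for d in counts.values() for i in d})
    if catalog is not None:
        items.sort(key=catalog.index)
    col_names = [_column_name(s, r) for (s, r) in columns]
    df = pd.DataFrame(0, index=items, columns=col_names, dtype=int)
    for (s, r), d in counts.items():
        for item, c in d.items():
            df.loc[item, _column_name(s, r)] = c
    if has_na_row:
        df.loc[NA_ROW] = [na_counts[c] for c in columns]

    column_totals = df.sum(axis=0)
    grand_total = int(column_totals.sum())

    # order item rows by descending total, ties by catalog order (stable sort
    # keeps the existing catalog-ordered index); NA row last
    item_rows = df.drop(index=[NA_ROW], errors="ignore")
    order = item_rows.sum(axis=1).sort_values(ascending=False, kind="stable").index
    df = df.loc[[*order, NA_ROW] if has_na_row else order]

    return CohortFrequencyTable(
        network_kind=network_kind,
        k=k,
        n_participants=n,
        counts=df,
        column_totals=column_totals,
        grand_total=grand_total,
    )


def summarize_distinct_targets(
    table: CohortFrequencyTable, statistic: str | None = None
) -> tuple[int, int]:
    """Number of distinct items appearing in the rank-1 / rank-2 columns.

    For a contemporaneous table the single strength statistic is implied;
    for a temporal table ``statistic`` must name ``"out_strength"`` or
    ``"in_strength"``.
    """
    stats = KIND_STATISTICS[table.network_kind]
    if statistic is None:
        if len(stats) > 1:
            raise ValueError(
                f"temporal tables need an explicit statistic from {stats}"
            )
        statistic = stats[0]
    if statistic not in stats:
        raise ValueError(f"{statistic!r} not in a {table.network_kind} table")
    items = table.counts.drop(index=[NA_ROW], errors="ignore")
    n1 = int((items[_column_name(statistic, 1)] > 0).sum())
    n2 = int((items[_column_name(statistic, 2)] > 0).sum())
    return n1, n2


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def render_networks(pair: NetworkPair, path: str | Path, seed: int = 0) -> list[Path]:
    """Schematic side-by-side plot of the contemporaneous and temporal networks.

    Nodes sit on a fixed circular layout (deterministic; ``seed`` kept for
    interface stability), edge width scales with |weight|, solid edges are
    positive and dashed negative.  Writes a single PNG without volatile
    metadata so identical inputs produce identical bytes.
    """
    path = Path(path)
    k = pair.k
    if not (np.any(pair.contemporaneous) or np.any(pair.temporal)):
        warnings.warn("both networks are empty; rendering nodes only", stacklevel=2)
    theta = 2 * np.pi * np.arange(k) / k + np.pi / 2
    pos = np.column_stack([np.cos(theta), np.sin(theta)])

    fig, axes = plt.subplots(1, 2, figsize=(11, 5.5))
    for ax, mat, title, directed in (
        (axes[0], pair.contemporaneous, "Contemporaneous (PCC)", False),
        (axes[1], pair.temporal, "Temporal (PDC)", True),
    ):
        wmax = np.abs(mat).max() or 1.0
        for i in range(k):
            for j in range(k):
                w = mat[i, j]
                if w == 0 or i == j:
                    continue
                if not directed and i < j:
                    continue  # draw undirected edges once
                style = "-" if w > 0 else "--"
                lw = 0.5 + 3.0 * abs(w) / wmax
                if directed:
                    ax.annotate(
                        "",
                        xy=pos[i], xytext=pos[j],
                        arrowprops=dict(
                            arrowstyle="-|>", linestyle=style, lw=lw,
                            color="#2c7bb6" if w > 0 else "#d7191c",
                            shrinkA=12, shrinkB=12,
                        ),
                    )
                else:
                    ax.plot(
                        [pos[i, 0], pos[j, 0]], [pos[i, 1], pos[j, 1]],
                        style, lw=lw, color="#2c7bb6" if w > 0 else "#d7191c",
                        zorder=1,
                    )
        ax.scatter(pos[:, 0], pos[:, 1], s=700, c="#ffffbf",
                   edgecolors="black", zorder=2)
        for label, (x, y) in zip(pair.items, pos):
            ax.text(x, y, label[:8], ha="center", va="center", fontsize=6, zorder=3)
        ax.set_title(title)
        ax.set_xlim(-1.35, 1.35)
        ax.set_ylim(-1.35, 1.35)
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    return [path]
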
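"""Item selection: reduce the full assessment battery to the k modeled items.

With 55 assessed symptoms and ~60 usable lag-1 pairs per person, a network
over all items is hopelessly underpowered, so each person's model is built on
the k items with the highest individual means (or, alternatively, the highest
variances) over their observed beeps.  The shipped presets are k = 15 and
k = 8.  Items with zero variance over observed beeps are ineligible — a
constant item carries no dynamic information and breaks estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ema import EMADataset, InsufficientDataError, descriptives

__all__ = ["SelectionRule", "ItemSelection", "select_items"]

METHODS = ("highest_mean", "highest_variance")


@dataclass(frozen=True)
class SelectionRule:
    """How to pick the modeled items: ranking statistic, item count, tie policy.

    Ties in the ranking statistic are broken by catalog order, which makes
    the selection a pure, reproducible function of the data and the rule.
    """

    method: str = "highest_mean"
    k: int = 15
    tie_policy: str = "catalog_order"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.tie_policy != "catalog_order":
            raise ValueError("only the 'catalog_order' tie policy is implemented")


@dataclass
class ItemSelection:
    participant_id: str
    rule: SelectionRule
    items: tuple[str, ...]
    statistic: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "method": self.rule.method,
            "k": self.rule.k,
            "items": list(self.items),
            "statistic": {c: float(v) for c, v in self.statistic.items()},
        }


def select_items(ds: EMADataset, rule: SelectionRule) -> ItemSelection:
    """Select the top-k items of ``ds`` under ``rule``.

    Eligibility: an item needs a defined ranking statistic and nonzero
    variance over its observed beeps.  The returned items are ordered by
    descending statistic, ties resolved toward earlier catalog position.
    Raises :class:`InsufficientDataError` when fewer than k items qualify.
    """
    if rule.k > ds.n_items:
        raise ValueError(f"k={rule.k} exceeds the {ds.n_items}-item catalog")
    stats = descriptives(ds)
    col = "mean" if rule.method == "highest_mean" else "variance"
    values = stats[col].to_numpy()
    eligible = ~np.isnan(values) & (stats["variance"].to_numpy() > 0)
    n_eligible = int(eligible.sum())
    if n_eligible < rule.k:
        raise InsufficientDataError(
            f"participant {ds.participant_id!r}: only {n_eligible} items are "
            f"eligible (defined {col}, nonzero variance) but k={rule.k}"
        )
    # stable sort on negated statistic keeps catalog order within ties
    idx = np.flatnonzero(eligible)
    order = idx[np.argsort(-values[idx], kind="stable")][: rule.k]
    items = tuple(ds.catalog.codes[j] for j in order)
    return ItemSelection(
        ds.participant_id,
        rule,
        items,
        {ds.catalog.codes[j]: float(values[j]) for j in order},
    )
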
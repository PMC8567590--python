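"""Core data model and IO for ecological momentary assessment (EMA) studies.

An EMA study prompts each participant several times a day ("beeps") for a
fixed number of days; at each beep a battery of symptom items is rated on a
bounded 0-100 visual-analogue scale.  This module provides the symptom
catalog, the beep schedule, the per-participant dataset container, CSV
reading/writing (long and wide layouts), per-item descriptive statistics,
and the construction of lag-1 observation pairs that feed the graphical VAR
estimator.

Missing data policy: a beep the participant did not answer is a row of
missing values; no imputation is performed anywhere.  Lag-1 pairs are kept
only when both the predictor beep and the outcome beep are fully observed on
the modeled items and are consecutive beeps of the same day — the process is
never lagged across the overnight gap.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "ValidationError",
    "InsufficientDataError",
    "SymptomCatalog",
    "Schedule",
    "EMADataset",
    "LaggedPairs",
    "Standardization",
    "default_catalog",
    "read_ema",
    "write_ema",
    "descriptives",
    "build_lagged_pairs",
    "standardize",
]

#: Sentinel for an unanswered item; all numeric storage uses NaN.
MISSING = np.nan

VALUE_MIN, VALUE_MAX = 0.0, 100.0


class ValidationError(ValueError):
    """Raised when input data violate the EMA data contract."""


class InsufficientDataError(ValueError):
    """Raised when too few usable observations remain for estimation."""


# ---------------------------------------------------------------------------
# Catalog and schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymptomCatalog:
    """Ordered catalog of assessed symptom items.

    The catalog order is canonical: it fixes column order in every matrix
    downstream and breaks ties deterministically wherever ranks collide.
    """

    item_ids: tuple[int, ...]
    codes: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.item_ids) == len(self.codes) == len(self.labels)):
            raise ValidationError("catalog fields must have equal length")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValidationError("catalog item_ids must be unique")
        if len(set(self.codes)) != len(self.codes):
            raise ValidationError("catalog codes must be unique")
        if any(i < 0 for i in self.item_ids):
            raise ValidationError("catalog item_ids must be >= 0")

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def index(self, code: str) -> int:
        """Position of ``code`` in catalog order."""
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"unknown item code: {code!r}") from None

    def indices(self, codes: Sequence[str]) -> np.ndarray:
        return np.asarray([self.index(c) for c in codes], dtype=int)

    @classmethod
    def from_entries(cls, entries: Iterable[tuple[int, str, str]]) -> "SymptomCatalog":
        ids, codes, labels = zip(*entries)
        return cls(tuple(ids), tuple(codes), tuple(labels))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SymptomCatalog":
        """Read a catalog CSV with columns item_id,code,label."""
        df = pd.read_csv(path, dtype={"item_id": int, "code": str, "label": str})
        required = {"item_id", "code", "label"}
        if not required.issubset(df.columns):
            raise ValidationError(f"catalog CSV needs columns {sorted(required)}")
        return cls.from_entries(df[["item_id", "code", "label"]].itertuples(index=False))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["item_id", "code", "label"])
            writer.writerows(zip(self.item_ids, self.codes, self.labels))


def default_catalog() -> SymptomCatalog:
    """The packaged 55-item eating-disorder EMA catalog."""
    ref = resources.files("idionet").joinpath("data/catalog_55.csv")
    with resources.as_file(ref) as path:
        return SymptomCatalog.from_csv(path)


@dataclass(frozen=True)
class Schedule:
    """Fixed beep schedule: ``beeps_per_day`` prompts on each of ``days`` days."""

    days: int
    beeps_per_day: int

    def __post_init__(self) -> None:
        if self.days <= 0 or self.beeps_per_day <= 0:
            raise ValidationError("schedule days and beeps_per_day must be positive")

    @property
    def total_beeps(self) -> int:
        return self.days * self.beeps_per_day

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """1-based (day, beep) indices in canonical row order."""
        day = np.repeat(np.arange(1, self.days + 1), self.beeps_per_day)
        beep = np.tile(np.arange(1, self.beeps_per_day + 1), self.days)
        return day, beep


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class EMADataset:
    """One participant's EMA time series on the full scheduled grid.

    ``values`` has one row per scheduled beep (``schedule.total_beeps`` rows,
    sorted by day then beep) and one column per catalog item; unanswered
    entries are NaN.  Every observed value lies in [0, 100].
    """

    participant_id: str
    schedule: Schedule
    catalog: SymptomCatalog
    values: np.ndarray
    day_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    beep_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        day, beep = self.schedule.grid()
        if self.day_index is None:
            self.day_index = day
        if self.beep_index is None:
            self.beep_index = beep
        self.day_index = np.asarray(self.day_index, dtype=int)
        self.beep_index = np.asarray(self.beep_index, dtype=int)
        n, p = self.schedule.total_beeps, len(self.catalog)
        if self.values.shape != (n, p):
            raise ValidationError(
                f"values must be {(n, p)} for participant {self.participant_id!r}, "
                f"got {self.values.shape}"
            )
        if not (np.array_equal(self.day_index, day) and np.array_equal(self.beep_index, beep)):
            raise ValidationError("rows must cover the full schedule in (day, beep) order")
        observed = self.values[~np.isnan(self.values)]
        if observed.size and (observed.min() < VALUE_MIN or observed.max() > VALUE_MAX):
            raise ValidationError(
                f"participant {self.participant_id!r} has values outside [0, 100]"
            )

    @property
    def n_items(self) -> int:
        return len(self.catalog)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def item_values(self, code: str) -> np.ndarray:
        return self.values[:, self.catalog.index(code)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.catalog.codes))
        df.insert(0, "beep", self.beep_index)
        df.insert(0, "day", self.day_index)
        df.insert(0, "participant", self.participant_id)
        return df


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

_META_COLS = ["participant", "day", "beep"]


def _validate_meta(df: pd.DataFrame, schedule: Schedule, path) -> None:
    for col in _META_COLS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    bad_day = ~df["day"].between(1, schedule.days)
    bad_beep = ~df["beep"].between(1, schedule.beeps_per_day)
    if bad_day.any() or bad_beep.any():
        row = int(df.index[bad_day | bad_beep][0]) + 2  # 1-based + header
        raise ValidationError(
            f"{path}: row {row} is outside the schedule "
            f"({schedule.days} days x {schedule.beeps_per_day} beeps)"
        )


def _check_range(values: pd.Series, path) -> None:
    bad = values.notna() & ~values.between(VALUE_MIN, VALUE_MAX)
    if bad.any():
        row = int(values.index[bad][0]) + 2
        raise ValidationError(f"{path}: row {row} has a value outside [0, 100]")


def read_ema(
    path: str | Path,
    format: str,
    catalog: SymptomCatalog,
    schedule: Schedule,
) -> list[EMADataset]:
    """Read an EMA CSV into one :class:`EMADataset` per participant.

    ``format`` is ``"long"`` (participant,day,beep,item_code,value) or
    ``"wide"`` (participant,day,beep,<code>,...).  Beeps absent from the file
    and empty cells become missing.  Values outside [0, 100], unknown item
    codes, out-of-schedule rows, and duplicate (participant, day, beep)
    records raise :class:`ValidationError`.
    """
    path = Path(path)
    if format not in ("long", "wide"):
        raise ValueError(f"format must be 'long' or 'wide', got {format!r}")
    df = pd.read_csv(path, dtype={"participant": str}, float_precision="round_trip")
    _validate_meta(df, schedule, path)

    if format == "long":
        if not {"item_code", "value"}.issubset(df.columns):
            raise ValidationError(f"{path}: long format needs item_code and value columns")
        unknown = set(df["item_code"]) - set(catalog.codes)
        if unknown:
            raise ValidationError(f"{path}: unknown item codes {sorted(unknown)}")
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        _check_range(df["value"], path)
        dup = df.duplicated(subset=["participant", "day", "beep", "item_code"])
        if dup.any():
            raise ValidationError(
                f"{path}: duplicate (participant, day, beep, item) at row "
                f"{int(df.index[dup][0]) + 2}"
            )
        wide = df.pivot_table(
            index=["participant", "day", "beep"],
            columns="item_code",
            values="value",
            aggfunc="first",
            dropna=False,
        )
        wide = wide.reindex(columns=list(catalog.codes))
        wide = wide.reset_index()
    else:
        unknown = set(df.columns) - set(_META_COLS) - set(catalog.codes)
        if unknown:
            raise ValidationError(f"{path}: unknown item columns {sorted(unknown)}")
        dup = df.duplicated(subset=["participant", "day", "beep"])
        if dup.any():
            raise ValidationError(
                f"{path}: duplicate (participant, day, beep) at row "
                f"{int(df.index[dup][0]) + 2}"
            )
        for code in catalog.codes:
            if code in df.columns:
                df[code] = pd.to_numeric(df[code], errors="coerce")
                _check_range(df[code], path)
            else:
                df[code] = np.nan
        wide = df[_META_COLS + list(catalog.codes)]

    datasets = []
    day, beep = schedule.grid()
    grid = pd.DataFrame({"day": day, "beep": beep})
    for pid, sub in wide.groupby("participant", sort=True):
        full = grid.merge(sub, on=["day", "beep"], how="left")
        values = full[list(catalog.codes)].to_numpy(dtype=float)
        datasets.append(EMADataset(str(pid), schedule, catalog, values))
    return datasets


def write_ema(datasets: Sequence[EMADataset], path: str | Path, format: str) -> Path:
    """Write datasets to a long or wide CSV re-readable by :func:`read_ema`.

    Missing entries are written as empty cells, never as 0.
    """
    if format not in ("long", "wide"):
        raise ValueError(f"format must be 'long' or 'wide', got {format!r}")
    if not datasets:
        raise ValueError("no datasets to write")
    path = Path(path)
    frames = [ds.to_frame() for ds in datasets]
    wide = pd.concat(frames, ignore_index=True)
    if format == "wide":
        wide.to_csv(path, index=False, na_rep="", float_format="%.17g")
    else:
        codes = list(datasets[0].catalog.codes)
        long = wide.melt(
            id_vars=_META_COLS, value_vars=codes, var_name="item_code", value_name="value"
        )
        # preserve beep-major order with items ordered as in the catalog
        long["_order"] = long["item_code"].map({c: i for i, c in enumerate(codes)})
        long = long.sort_values(_META_COLS + ["_order"], kind="stable").drop(columns="_order")
        long.to_csv(path, index=False, na_rep="", float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------


def descriptives(ds: EMADataset) -> pd.DataFrame:
    """Per-item mean, sd, variance, n_obs and percent missing.

    Statistics use observed values only; sd and variance use the n-1
    denominator.  Items with no observations get NaN statistics; items with a
    single observation get a defined mean but NaN variance.
    """
    rows = []
    n_total = ds.schedule.total_beeps
    for j, code in enumerate(ds.catalog.codes):
        col = ds.values[:, j]
        obs = col[~np.isnan(col)]
        n_obs = obs.size
        mean = float(obs.mean()) if n_obs else np.nan
        var = float(obs.var(ddof=1)) if n_obs >= 2 else np.nan
        rows.append(
            {
                "item": code,
                "mean": mean,
                "sd": np.sqrt(var) if n_obs >= 2 else np.nan,
                "variance": var,
                "n_obs": n_obs,
                "pct_missing": 100.0 * (n_total - n_obs) / n_total,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lag-1 pair construction and standardization
# ---------------------------------------------------------------------------


@dataclass
class LaggedPairs:
    """Paired design matrices for the lag-1 model: row t of ``x_now`` is the
    beep immediately following row t of ``x_lag`` within the same day."""

    participant_id: str
    items: tuple[str, ...]
    x_lag: np.ndarray
    x_now: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.x_now.shape[0]

    @property
    def n_items(self) -> int:
        return len(self.items)


def build_lagged_pairs(
    ds: EMADataset, items: Sequence[str], detrend: bool = False
) -> LaggedPairs:
    """Extract all usable (t-1, t) beep pairs for the selected items.

    A pair is usable only when both beeps are fully observed on ``items``,
    fall on the same day, and have consecutive beep indices.  Overnight
    transitions (last beep of a day to first beep of the next) are never
    paired.  With ``detrend=True`` a per-item linear trend over the
    scheduled beep index is removed first (off by default; slow drifts over
    the study window otherwise masquerade as autoregression).  Raises
    :class:`InsufficientDataError` when fewer than ``len(items) + 2`` pairs
    remain.
    """
    items = tuple(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    cols = ds.catalog.indices(items)
    sub = ds.values[:, cols]
    if detrend:
        sub = sub.copy()
        t = np.arange(sub.shape[0], dtype=float)
        for j in range(sub.shape[1]):
            obs = ~np.isnan(sub[:, j])
            if obs.sum() >= 3 and t[obs].std() > 0:
                slope, intercept = np.polyfit(t[obs], sub[obs, j], 1)
                sub[:, j] -= slope * t + intercept - sub[obs, j].mean()
    complete = ~np.isnan(sub).any(axis=1)
    same_day = ds.day_index[1:] == ds.day_index[:-1]
    consecutive = ds.beep_index[1:] == ds.beep_index[:-1] + 1
    ok = complete[:-1] & complete[1:] & same_day & consecutive
    x_lag = sub[:-1][ok]
    x_now = sub[1:][ok]
    n_pairs = int(ok.sum())
    if n_pairs < len(items) + 2:
        raise InsufficientDataError(
            f"participant {ds.participant_id!r}: only {n_pairs} usable lag-1 pairs "
            f"for {len(items)} items (need >= {len(items) + 2}); "
            "use fewer items or collect more beeps"
        )
    return LaggedPairs(ds.participant_id, items, x_lag, x_now)


@dataclass(frozen=True)
class Standardization:
    """Per-item centering/scaling constants; invertible record of the z-transform."""

    items: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.sd + self.mean


def standardize(pairs: LaggedPairs) -> tuple[LaggedPairs, Standardization]:
    """Within-person z-score both design matrices with shared constants.

    The mean and sd (n-1 denominator) of each item are computed over the
    stacked rows of ``x_lag`` and ``x_now``, so the same affine transform is
    applied to predictor and outcome.  Re-standardizing standardized pairs is
    a no-op.  An item with zero variance over the used rows cannot enter the
    model and raises :class:`ValidationError` naming it.
    """
    stacked = np.vstack([pairs.x_lag, pairs.x_now])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [pairs.items[j] for j in zero]
        raise ValidationError(
            f"participant {pairs.participant_id!r}: item(s) {names} have no "
            "variability over the modeled beeps; cannot be modeled"
        )
    out = LaggedPairs(
        pairs.participant_id,
        pairs.items,
        (pairs.x_lag - mean) / sd,
        (pairs.x_now - mean) / sd,
    )
    return out, Standardization(pairs.items, mean, sd)
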
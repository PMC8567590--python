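"""End-to-end run orchestration: read -> select items -> fit -> targets -> tables.

A run is fully described by a :class:`RunConfig` (serializable to YAML); the
pipeline echoes the config into the output directory so any run can be
reproduced exactly from its own artifacts.  Per-participant failures are
caught, logged, and turned into NA target selections — a participant whose
network cannot be estimated still appears in the cohort accounting.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .centrality import TargetSelection, compute_centrality, select_targets
from .ema import (
    EMADataset,
    Schedule,
    SymptomCatalog,
    default_catalog,
    read_ema,
    standardize,
    build_lagged_pairs,
)
from .gvar import fit_gvar_path, to_networks
from .report import KIND_STATISTICS, render_networks, tabulate
from .selection import SelectionRule, select_items

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

log = logging.getLogger("idionet")

#: Warn (don't refuse) when candidate parameters per usable pair exceed this.
OVERPARAM_RATIO = 4.0


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    input_path: str
    output_dir: str
    input_format: str = "wide"
    catalog_path: str | None = None  # None -> packaged 55-item catalog
    days: int = 15
    beeps_per_day: int = 5
    selection_method: str = "highest_mean"
    detrend: bool = False
    k_presets: list[int] = field(default_factory=lambda: [15, 8])
    n_lambda: int = 10
    gamma: float = 0.5
    seed: int = 0
    render_figures: bool = False

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunResult:
    config: RunConfig
    n_participants: int
    n_failed: int
    tables: dict[tuple[str, int], object]  # (network_kind, k) -> CohortFrequencyTable
    output_dir: Path


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def _na_selections(pid: str) -> dict[str, TargetSelection]:
    return {
        stat: TargetSelection(pid, stat, (), (), is_na=True,
                              tie_note="model estimation failed")
        for kind in KIND_STATISTICS
        for stat in KIND_STATISTICS[kind]
    }


def _fit_participant(
    ds: EMADataset,
    k: int,
    config: RunConfig,
    outdir: Path,
) -> tuple[dict[str, TargetSelection], dict | None]:
    """Fit one participant at one k; returns selections and a fit artifact."""
    pid = ds.participant_id
    rule = SelectionRule(method=config.selection_method, k=k)
    selection = select_items(ds, rule)
    pairs = build_lagged_pairs(ds, selection.items, detrend=config.detrend)
    n_params = k * k + k * (k + 1) // 2
    if n_params / pairs.n_pairs > OVERPARAM_RATIO:
        log.warning(
            "participant %s (k=%d): %d candidate parameters for %d pairs "
            "(ratio %.1f); estimates may be unstable",
            pid, k, n_params, pairs.n_pairs, n_params / pairs.n_pairs,
        )
    std_pairs, transform = standardize(pairs)
    t0 = time.perf_counter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = fit_gvar_path(
            std_pairs, n_lambda=config.n_lambda, gamma=config.gamma
        )
    elapsed = time.perf_counter() - t0
    log.info(
        "participant %s (k=%d): EBIC fit in %.2fs, n_pairs=%d, df=%d, "
        "lambda=(%.4f, %.4f), converged=%s",
        pid, k, elapsed, fit.n_pairs, fit.df, fit.lambda_B, fit.lambda_K,
        fit.converged,
    )
    nets = to_networks(fit)
    cent = compute_centrality(nets)
    selections = {
        stat: select_targets(cent, stat, pid)
        for kind in KIND_STATISTICS
        for stat in KIND_STATISTICS[kind]
    }

    artifact = {
        "participant": pid,
        "k": k,
        "selected_items": selection.to_dict(),
        "standardization": {
            "mean": transform.mean.tolist(),
            "sd": transform.sd.tolist(),
        },
        "fit": fit.to_dict(),
        "centrality": cent.to_frame().to_dict(orient="records"),
    }
    fit_dir = outdir / "fits"
    fit_dir.mkdir(exist_ok=True)
    with open(fit_dir / f"{pid}_k{k}.json", "w", encoding="utf-8") as fh:
        json.dump(artifact, fh, indent=1)

    edges = []
    for kind, mat in (("temporal", nets.temporal), ("contemporaneous", nets.contemporaneous)):
        for i, to_item in enumerate(nets.items):
            for j, from_item in enumerate(nets.items):
                w = mat[i, j]
                if w != 0 and (kind == "temporal" or j < i):
                    edges.append(
                        {"from": from_item, "to": to_item, "weight": w,
                         "network_type": kind}
                    )
    pd.DataFrame(edges, columns=["from", "to", "weight", "network_type"]).to_csv(
        fit_dir / f"{pid}_k{k}_edges.csv", index=False
    )

    if config.render_figures:
        fig_dir = outdir / "figures"
        fig_dir.mkdir(exist_ok=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            render_networks(nets, fig_dir / f"{pid}_k{k}.png", seed=config.seed)
    return selections, artifact


def run_pipeline(
    config: RunConfig,
    datasets: list[EMADataset] | None = None,
) -> RunResult:
    """Execute the full analysis described by ``config``.

    ``datasets`` may be supplied directly (e.g. fresh from the simulator);
    otherwise they are read from ``config.input_path``.  Outputs: per-
    participant fit JSON and edge CSVs, per-participant target CSV, one
    cohort frequency table per (network kind, k) as CSV and Markdown, the
    echoed config, and a log.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    try:
        config.to_yaml(outdir / "config.yaml")
        if datasets is None:
            catalog = (
                SymptomCatalog.from_csv(config.catalog_path)
                if config.catalog_path
                else default_catalog()
            )
            schedule = Schedule(config.days, config.beeps_per_day)
            input_path = Path(config.input_path)
            if not input_path.exists():
                raise FileNotFoundError(f"input not found: {input_path}")
            datasets = read_ema(input_path, config.input_format, catalog, schedule)
        if not datasets:
            raise ValueError("no participants in input")
        log.info("loaded %d participants", len(datasets))

        all_rows = []
        tables = {}
        n_failed = 0
        for k in config.k_presets:
            selections_by_stat: dict[str, list[TargetSelection]] = {
                stat: [] for kind in KIND_STATISTICS for stat in KIND_STATISTICS[kind]
            }
            for ds in datasets:
                try:
                    sels, _ = _fit_participant(ds, k, config, outdir)
                except Exception as err:  # participant-level containment
                    log.error(
                        "participant %s (k=%d) failed: %s", ds.participant_id, k, err
                    )
                    n_failed += 1
                    sels = _na_selections(ds.participant_id)
                for stat, sel in sels.items():
                    selections_by_stat[stat].append(sel)
                    for rank, items in ((1, sel.rank1), (2, sel.rank2)):
                        if sel.is_na:
                            if rank == 1:
                                all_rows.append(
                                    {"participant": ds.participant_id, "k": k,
                                     "statistic": stat, "rank": "NA",
                                     "item_code": "", "value": "",
                                     "is_na": True, "tie": sel.tie_note}
                                )
                            continue
                        for item in items:
                            all_rows.append(
                                {"participant": ds.participant_id, "k": k,
                                 "statistic": stat, "rank": rank,
                                 "item_code": item,
                                 "value": sel.values.get(item, ""),
                                 "is_na": False, "tie": sel.tie_note}
                            )
            for kind, stats in KIND_STATISTICS.items():
                sels = [s for stat in stats for s in selections_by_stat[stat]]
                table = tabulate(sels, kind, k, catalog=datasets[0].catalog)
                tables[(kind, k)] = table
                stem = outdir / f"cohort_{kind}_k{k}"
                table.to_csv(stem.with_suffix(".csv"))
                stem.with_suffix(".md").write_text(table.to_markdown() + "\n", encoding="utf-8")
                log.info(
                    "cohort table %s k=%d: grand total %d", kind, k, table.grand_total
                )

        pd.DataFrame(all_rows).to_csv(outdir / "targets.csv", index=False)
        n_participants = len(datasets)
        summary = {
            "n_participants": n_participants,
            "n_failed_fits": n_failed,
            "k_presets": config.k_presets,
            "tables": {
                f"{kind}_k{k}": {
                    "grand_total": t.grand_total,
                    "column_totals": {c: int(v) for c, v in t.column_totals.items()},
                }
                for (kind, k), t in tables.items()
            },
        }
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1)
        if n_failed >= n_participants * len(config.k_presets) and n_participants:
            raise RuntimeError("all participant fits failed; see run.log")
        return RunResult(config, n_participants, n_failed, tables, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()
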
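"""Sort-record serialization, pipeline configuration, and the end-to-end run.

Sort records travel as long-layout CSV (one row per placed item:
participant_id, condition, item_id, x, y, canvas_w, canvas_h, moved_all); a
wide layout (one row per participant, ``<item>_x`` / ``<item>_y`` columns)
is accepted behind a flag.  ``run_pipeline`` sequences synthetic cohort →
exclusion filters → metrics → clustering → inference and emits a JSON
report plus CSV tables, reproducible from (config, seed): every output
names the config hash and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from sortalign import clustering, inference, metrics, shapes
from sortalign.inference import FitError
from sortalign.simulate import (
    SorterConfig,
    SortRecord,
    default_condition_params,
    simulate_cohort,
)

log = logging.getLogger("sortalign")

SORT_COLUMNS = [
    "participant_id", "condition", "item_id", "x", "y",
    "canvas_w", "canvas_h", "moved_all",
]


class SchemaError(ValueError):
    """CSV rows violating the sort-record schema (reported with row numbers)."""


def write_sorts(records: Sequence[SortRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for item, (x, y) in zip(rec.item_ids, rec.positions):
            rows.append(
                {"participant_id": rec.participant_id, "condition": rec.condition,
                 "item_id": item, "x": x, "y": y, "canvas_w": rec.canvas_w,
                 "canvas_h": rec.canvas_h, "moved_all": rec.moved_all}
            )
    pd.DataFrame(rows, columns=SORT_COLUMNS).to_csv(path, index=False)


def read_sorts(path: str | Path, wide: bool = False) -> list[SortRecord]:
    """Read and validate sort records from CSV (long layout by default,
    wide with ``wide=True``).  Schema violations name the offending rows."""
    df = pd.read_csv(path, float_precision="round_trip")
    if wide:
        df = _wide_to_long(df)
    missing = [c for c in SORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    bad = df.index[df[["participant_id", "item_id", "x", "y"]].isna().any(axis=1)]
    if len(bad):
        raise SchemaError(f"rows with missing required fields (0-based data rows): {list(bad)}")
    dup = df.duplicated(subset=["participant_id", "item_id"])
    if dup.any():
        raise SchemaError(f"duplicate (participant, item) rows: {list(df.index[dup])}")
    off = df.index[
        (df["x"] < 0) | (df["x"] > df["canvas_w"]) | (df["y"] < 0) | (df["y"] > df["canvas_h"])
    ]
    if len(off):
        raise SchemaError(f"off-canvas coordinates in rows: {list(off)}")
    records = []
    for pid, grp in df.groupby("participant_id", sort=False):
        records.append(
            SortRecord(
                participant_id=str(pid),
                condition=str(grp["condition"].iloc[0]),
                item_ids=tuple(grp["item_id"].astype(str)),
                positions=tuple(zip(grp["x"].astype(float), grp["y"].astype(float))),
                canvas_w=int(grp["canvas_w"].iloc[0]),
                canvas_h=int(grp["canvas_h"].iloc[0]),
                moved_all=bool(grp["moved_all"].iloc[0]),
            )
        )
    return records


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    item_cols = [c[:-2] for c in df.columns if c.endswith("_x") and f"{c[:-2]}_y" in df.columns]
    if not item_cols:
        raise SchemaError("wide layout: no <item>_x/<item>_y column pairs found")
    rows = []
    for _, r in df.iterrows():
        for item in item_cols:
            rows.append(
                {"participant_id": r["participant_id"], "condition": r["condition"],
                 "item_id": item, "x": r[f"{item}_x"], "y": r[f"{item}_y"],
                 "canvas_w": r["canvas_w"], "canvas_h": r["canvas_h"],
                 "moved_all": r.get("moved_all", True)}
            )
    return pd.DataFrame(rows, columns=SORT_COLUMNS)


@dataclass
class PipelineConfig:
    """End-to-end run configuration; round-trips losslessly through YAML."""

    mode: str = "synthetic"  # "1", "2", or "synthetic"
    seed: int = 0
    n_per_condition: int = 40
    canvas_w: int = 1024
    canvas_h: int = 768
    k_min: int = 2
    k_max: int = 10
    condition_params: dict[str, dict] = field(
        default_factory=lambda: {
            c: {k: v for k, v in dataclasses.asdict(cfg).items() if k != "rng_seed"}
            for c, cfg in default_condition_params().items()
        }
    )

    def sorter_configs(self) -> dict[str, SorterConfig]:
        return {
            c: SorterConfig(**{**p, "canvas_w": self.canvas_w, "canvas_h": self.canvas_h})
            for c, p in self.condition_params.items()
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def participant_table(
    cohort: Sequence[SortRecord],
    category_of: Mapping[str, str],
    k_range: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant aggregates (categoricality, mean alignment, bridged
    categoricality, cluster count) and the dyad table."""
    result = metrics.alignment_matrix(cohort, category_of)
    dyads = pd.DataFrame([vars(d) for d in result.dyads])
    cat = {r.participant_id: metrics.categoricality(r, category_of).score for r in cohort}
    bridged: dict[str, list[float]] = {}
    for d in result.dyads:
        bridged.setdefault(d.id_i, []).append(d.cat_min)
        bridged.setdefault(d.id_j, []).append(d.cat_min)
    clusters, _ = clustering.cluster_counts(cohort, k_range)
    table = pd.DataFrame(
        {"participant_id": result.participant_ids,
         "condition": result.conditions,
         "categoricality": [cat[p] for p in result.participant_ids],
         "mean_alignment": result.mean_z,
         "bridged_min_cat": [float(np.mean(bridged[p])) for p in result.participant_ids]}
    ).merge(clusters[["participant_id", "n_clusters", "avg_silhouette"]], on="participant_id")
    return table, dyads


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run cohort generation → filters → metrics → clustering → inference.

    Returns the JSON-serializable report; when ``out_dir`` is given, writes
    report.json plus sorts/participants/dyads CSV tables there.
    """
    if cfg.mode in ("1", "2", 1, 2):
        stim = shapes.generate_stimuli(int(cfg.mode), seed=cfg.seed)
        sort_set = stim["sort_set"]
        items: Sequence[str] | shapes.StimulusSet = sort_set
        category_of = sort_set.category_of()
    elif cfg.mode == "synthetic":
        items = [f"A{i:02d}" for i in range(1, 11)] + [f"B{i:02d}" for i in range(1, 11)]
        category_of = {i: i[0] for i in items}
    else:
        raise ValueError(f"mode must be '1', '2' or 'synthetic', got {cfg.mode!r}")

    cohort = simulate_cohort(
        cfg.n_per_condition, cfg.sorter_configs(), master_seed=cfg.seed,
        items=items, category_of=category_of,
    )
    log.info("simulated %d sorts across %d conditions", len(cohort),
             len(cfg.condition_params))
    kept, reasons = metrics.participant_filter(cohort)
    excluded = {p: r for p, r in reasons.items() if r != "ok"}
    log.info("exclusions: %d of %d", len(excluded), len(cohort))

    k_range = range(cfg.k_min, cfg.k_max + 1)
    table, dyads = participant_table(kept, category_of, k_range)
    _, cluster_summary = clustering.cluster_counts(kept, k_range)

    conditions = sorted(table["condition"].unique())
    analyses: dict = {}
    if len(conditions) < 2:
        analyses["note"] = "no contrasts (single condition)"
    else:
        for pair in combinations(conditions, 2):
            key = f"{pair[0]}_vs_{pair[1]}"
            entry: dict = {}
            for outcome in ("mean_alignment", "categoricality"):
                entry[outcome] = _try_fit(
                    inference.condition_effect, table, outcome=outcome, contrast=pair
                )
            entry["n_clusters_poisson"] = _try_fit(
                inference.cluster_count_model, table, contrast=pair
            )
            entry["two_cluster_logistic"] = _try_fit(
                inference.two_cluster_model, table, contrast=pair
            )
            entry["mediation_by_categoricality"] = _try_fit(
                inference.mediation, table, covariate="bridged_min_cat", contrast=pair
            )
            analyses[key] = entry
        analyses["bridge_correlations"] = _try_fit(inference.bridge_correlations, dyads, table)

    report = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "mode": str(cfg.mode),
        "n_simulated": len(cohort),
        "n_kept": len(kept),
        "exclusions": excluded,
        "condition_summary": {
            c: {
                "n": int((table["condition"] == c).sum()),
                "mean_alignment": float(table.loc[table["condition"] == c, "mean_alignment"].mean()),
                "mean_categoricality": float(table.loc[table["condition"] == c, "categoricality"].mean()),
                "mean_clusters": float(table.loc[table["condition"] == c, "n_clusters"].mean()),
                "two_cluster_prop": float((table.loc[table["condition"] == c, "n_clusters"] == 2).mean()),
            }
            for c in conditions
        },
        "analyses": analyses,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = f"{cfg.config_hash}-seed{cfg.seed}"
        write_sorts(cohort, out / f"sorts-{stamp}.csv")
        table.assign(config_hash=cfg.config_hash, seed=cfg.seed).to_csv(
            out / f"participants-{stamp}.csv", index=False
        )
        dyads.assign(config_hash=cfg.config_hash, seed=cfg.seed).to_csv(
            out / f"dyads-{stamp}.csv", index=False
        )
        (out / f"report-{stamp}.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _try_fit(fn, *args, **kwargs):
    try:
        result = fn(*args, **kwargs)
    except (FitError, ValueError) as exc:
        return {"error": str(exc)}
    if hasattr(result, "to_dict"):
        return result.to_dict()
    return result
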
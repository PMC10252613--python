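"""End-to-end orchestration: synth -> segment -> features -> cluster -> stats.

One :class:`RunConfig` (one mandatory master seed) drives the whole
workflow per modality arm:

1. synthesize dense fields per induction timepoint until the configured
   number of accepted single cells (150-200 by default) is reached;
2. segment each field with the sliding-window screen;
3. extract the modality's feature set from every accepted crop;
4. min-max normalize, select k by the elbow rule (or honour a fixed k),
   fit K-means++ and map clusters to differentiation states;
5. build the per-day proportion table and annotate day-to-day feature
   differences with Z-tests.

Every stage seed is derived deterministically from the master seed, so an
identical config reproduces every output bit for bit (the run manifest
hashes all of them).
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (
    AmbiguousStateError,
    cluster_cells,
    assign_states,
    proportion_table,
)
from .features import (
    FeatureFailureError,
    FeatureTable,
    MaskFailureError,
    build_mask,
    extract_features,
    normalize_features,
)
from .segment import ScreenParams, detect_cells, estimate_window_matrix
from .stats import significance_labels, ztest_two_means, ztest_two_proportions
from .synth import (
    StateConfig,
    TimepointMixture,
    default_mixtures,
    default_state_configs,
    generate_field,
)

__all__ = ["RunConfig", "PipelineStageError", "run", "load_config"]

logger = logging.getLogger("stemstate.pipeline")

#: feature of interest per modality for the day-to-day Z-tests
_STATS_FEATURE = {"FLIM_A2": "a2_peak", "SRS": "mean_gray"}


class PipelineStageError(RuntimeError):
    """A stage failed; the message carries the stage and field/cell context."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run.

    ``cells_per_timepoint`` is the accepted-cell target range per timepoint
    per modality: fields are synthesized until the lower bound is reached
    (or ``max_fields_per_timepoint`` exhausted) and the list is truncated
    at the upper bound.
    """

    seed: int
    modalities: tuple[str, ...] = ("FLIM_A2",)
    field_height: int = 512
    field_width: int = 512
    cells_per_field: int = 18
    cells_per_timepoint: tuple[int, int] = (150, 200)
    max_fields_per_timepoint: int = 14
    k: int | str = "auto"
    mixtures: tuple[TimepointMixture, ...] = dc_field(
        default_factory=lambda: tuple(default_mixtures())
    )
    state_configs: dict[str, StateConfig] = dc_field(default_factory=default_state_configs)
    screen_params: ScreenParams = dc_field(default_factory=ScreenParams)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.cells_per_timepoint
        if not 1 <= lo <= hi:
            raise ValueError("cells_per_timepoint must be an increasing range")
        unknown = [m for m in self.modalities if m not in ("FLIM_A2", "SRS")]
        if unknown:
            raise ValueError(f"unknown modalities: {unknown}")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a TOML file ([run], optional [synth] tables)."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    run_tbl = doc.get("run", {})
    kwargs: dict = {}
    for key in (
        "seed",
        "field_height",
        "field_width",
        "cells_per_field",
        "max_fields_per_timepoint",
        "k",
        "out_dir",
    ):
        if key in run_tbl:
            kwargs[key] = run_tbl[key]
    if "modalities" in run_tbl:
        kwargs["modalities"] = tuple(run_tbl["modalities"])
    if "cells_per_timepoint" in run_tbl:
        kwargs["cells_per_timepoint"] = tuple(run_tbl["cells_per_timepoint"])
    synth_tbl = doc.get("synth", {})
    if "mixtures" in synth_tbl:
        kwargs["mixtures"] = tuple(
            TimepointMixture(int(m["day"]), dict(m["fractions"]))
            for m in synth_tbl["mixtures"]
        )
    if "states" in synth_tbl:
        kwargs["state_configs"] = {
            name: StateConfig(state_name=name, **{
                k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()
            })
            for name, cfg in synth_tbl["states"].items()
        }
    if "segment" in doc:
        kwargs["screen_params"] = ScreenParams(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in doc["segment"].items()
        })
    if "seed" not in kwargs:
        raise ValueError("config must set run.seed")
    return RunConfig(**kwargs)


def _derive_seed(ss: np.random.SeedSequence, *keys: int) -> int:
    child = np.random.SeedSequence(entropy=ss.entropy, spawn_key=tuple(keys))
    return int(child.generate_state(1)[0] % (2**31))


def _collect_timepoint(
    config: RunConfig, modality: str, mix: TimepointMixture, mod_idx: int, day_idx: int
) -> tuple[list[dict], dict]:
    """Generate/segment/extract until the accepted-cell target is met."""
    ss = np.random.SeedSequence(config.seed)
    lo, hi = config.cells_per_timepoint
    rows: list[dict] = []
    excluded: list[dict] = []
    n_accepted = 0
    fields_used = 0
    wsm = None
    for field_idx in range(config.max_fields_per_timepoint):
        if n_accepted >= lo:
            break
        seed_f = _derive_seed(ss, mod_idx, day_idx, field_idx)
        try:
            field, gt = generate_field(
                config.field_width,
                config.field_height,
                config.cells_per_field,
                mix,
                config.state_configs,
                modality,
                seed=seed_f,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(
                f"synth failed (modality={modality}, day={mix.day}, "
                f"field={field_idx}): {exc}"
            ) from exc
        if wsm is None:
            sizes = [
                (float(np.ptp(r.cell_polygon[:, 0])), float(np.ptp(r.cell_polygon[:, 1])))
                for r in gt.records
            ]
            wsm = estimate_window_matrix(sizes)
        try:
            result = detect_cells(field, wsm, config.screen_params)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(
                f"segment failed (modality={modality}, day={mix.day}, "
                f"field={field_idx}): {exc}"
            ) from exc
        for det in result.detections:
            top, left, h, w = det.window
            crop = field.pixels[top : top + h, left : left + w]
            cell_id = f"d{mix.day}_f{field_idx}_c{len(rows) + len(excluded)}"
            try:
                mask = build_mask(crop)
                feats = extract_features(crop, modality, mask)
            except (MaskFailureError, FeatureFailureError) as exc:
                excluded.append({"cell_id": cell_id, "reason": str(exc)})
                continue
            rows.append(
                {"cell_id": cell_id, "day": mix.day, "field": field_idx, **feats}
            )
            n_accepted += 1
        fields_used = field_idx + 1
    rows = rows[:hi]
    logger.info(
        "timepoint day=%s modality=%s: %d cells accepted from %d fields "
        "(%d excluded)",
        mix.day, modality, len(rows), fields_used, len(excluded),
    )
    diag = {
        "day": mix.day,
        "fields_used": fields_used,
        "cells_accepted": len(rows),
        "cells_excluded": len(excluded),
        "excluded": excluded,
    }
    return rows, diag


def _day_stats(df: pd.DataFrame, feature: str) -> list[dict]:
    """Two-sided Z-tests on the per-cell feature between consecutive days."""
    out = []
    days = sorted(df["day"].unique())
    for d1, d2 in zip(days[:-1], days[1:]):
        g1 = df.loc[df["day"] == d1, feature]
        g2 = df.loc[df["day"] == d2, feature]
        res = ztest_two_means(
            g1.mean(), g1.std(ddof=1), len(g1), g2.mean(), g2.std(ddof=1), len(g2)
        )
        out.append(
            {
                "feature": feature,
                "day_a": int(d1),
                "day_b": int(d2),
                "z": res.statistic,
                "p_value": res.p_value,
                "label": significance_labels(res.p_value),
            }
        )
    return out


def _run_modality(config: RunConfig, modality: str, mod_idx: int) -> dict:
    all_rows: list[dict] = []
    diagnostics = []
    for day_idx, mix in enumerate(config.mixtures):
        rows, diag = _collect_timepoint(config, modality, mix, mod_idx, day_idx)
        all_rows.extend(rows)
        diagnostics.append(diag)
    df = pd.DataFrame(all_rows)
    if df.empty:
        raise PipelineStageError(f"no cells accepted for modality {modality}")
    feature_cols = tuple(c for c in df.columns if c not in ("cell_id", "day", "field"))
    table = normalize_features(FeatureTable(df, feature_cols))
    try:
        model, elbow = cluster_cells(table, k=config.k, seed=_derive_seed(
            np.random.SeedSequence(config.seed), mod_idx, 9999
        ))
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(f"cluster failed (modality={modality}): {exc}") from exc

    days = df["day"].to_numpy()
    fields = df["field"].to_numpy()
    try:
        state_map = assign_states(model.assignments, days, k=model.k) if model.k == 3 else None
    except AmbiguousStateError:
        state_map = None
    props = proportion_table(model.assignments, days, fields, k=model.k)

    stats_rows = _day_stats(df, _STATS_FEATURE[modality])
    # undifferentiated-cluster occupancy, first vs last day
    if state_map is not None:
        undiff_cluster = next(c for c, s in state_map.items() if s == "undiff")
        first, last = df["day"].min(), df["day"].max()
        x1 = int(((days == first) & (model.assignments == undiff_cluster)).sum())
        n1 = int((days == first).sum())
        x2 = int(((days == last) & (model.assignments == undiff_cluster)).sum())
        n2 = int((days == last).sum())
        res = ztest_two_proportions(x1, n1, x2, n2)
        stats_rows.append(
            {
                "feature": "undiff_fraction",
                "day_a": int(first),
                "day_b": int(last),
                "z": res.statistic,
                "p_value": res.p_value,
                "label": significance_labels(res.p_value),
            }
        )

    report = {
        "modality": modality,
        "timepoints": [
            {k: v for k, v in d.items() if k != "excluded"} for d in diagnostics
        ],
        "n_cells": int(len(df)),
        "n_excluded": int(sum(d["cells_excluded"] for d in diagnostics)),
        "k": int(model.k),
        "elbow": None
        if elbow is None
        else {
            "k_range": list(elbow.k_range),
            "wcss_curve": [round(w, 9) for w in elbow.wcss_curve],
            "k_selected": elbow.k_selected,
            "flat": elbow.flat,
        },
        "wcss": round(float(model.wcss), 9),
        "centroids": np.round(model.centroids, 9).tolist(),
        "state_map": None
        if state_map is None
        else {str(c): s for c, s in sorted(state_map.items())},
        "proportions": props.rows.round(9).to_dict(orient="records"),
        "stats": [
            {**r, "z": round(r["z"], 9), "p_value": round(r["p_value"], 12)}
            for r in stats_rows
        ],
    }
    artifacts = {
        "features": df,
        "proportions": props.rows,
        "assignments": pd.DataFrame(
            {"cell_id": df["cell_id"], "cluster": model.assignments}
        ),
    }
    return {"report": report, "artifacts": artifacts}


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report with its manifest.

    The manifest maps every produced artifact to a SHA-256 of its canonical
    serialization; identical configs (same seed) give identical manifests.
    When ``config.out_dir`` is set the artifacts are also written there
    (CSV tables plus ``report.json``, ``manifest.json`` and ``run.log``).
    """
    log_handler = None
    if config.out_dir is not None:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(Path(config.out_dir) / "run.log", mode="w")
        log_handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(log_handler)
        logger.setLevel(logging.INFO)
    per_modality = {}
    manifest: dict[str, str] = {}
    for mod_idx, modality in enumerate(config.modalities):
        result = _run_modality(config, modality, mod_idx)
        per_modality[modality] = result
        for name, frame in result["artifacts"].items():
            csv_bytes = frame.to_csv(index=False, float_format="%.9g").encode()
            manifest[f"{modality}/{name}.csv"] = _sha256(csv_bytes)

    report = {
        "stemstate_version": __version__,
        "seed": config.seed,
        "modalities": {m: r["report"] for m, r in per_modality.items()},
    }
    report_bytes = json.dumps(report, sort_keys=True).encode()
    manifest["report.json"] = _sha256(report_bytes)
    report["manifest"] = manifest
    report["manifest_hash"] = _sha256(json.dumps(manifest, sort_keys=True).encode())

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for modality, result in per_modality.items():
            mdir = out / modality
            mdir.mkdir(exist_ok=True)
            for name, frame in result["artifacts"].items():
                frame.to_csv(mdir / f"{name}.csv", index=False, float_format="%.9g")
        (out / "report.json").write_bytes(report_bytes)
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    if log_handler is not None:
        logger.removeHandler(log_handler)
        log_handler.close()
    return report


def scaled_down(config: RunConfig, factor: int = 2) -> RunConfig:
    """A cheaper variant of a config (fewer cells per timepoint), for tests."""
    lo, hi = config.cells_per_timepoint
    return replace(
        config,
        cells_per_timepoint=(max(10, lo // factor), max(10, hi // factor)),
        max_fields_per_timepoint=max(2, config.max_fields_per_timepoint // factor),
    )
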
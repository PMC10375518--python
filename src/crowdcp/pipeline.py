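"""End-to-end pipeline driver.

Stages form a prefix-closed chain::

    simulate -> aggregate -> render -> clean -> consensus -> evaluate -> tune

``simulate`` writes a synthetic record extract and its truth table;
``aggregate`` the tidy series CSV; ``render`` the PNGs, the coordinates
manifest, and — because line drawing needs the image geometry — the
simulated volunteer and expert annotation-line tables; ``clean`` the
first-attempt/merged lines; ``consensus`` the label table; ``evaluate``
the confusion counts and metrics JSON; ``tune`` the 266-row grid CSV.

Re-running with an identical config and seed reproduces identical CSV
outputs byte for byte.  Every stage records its artefacts and the
sha256 of its inputs in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import cleaning, consensus, evaluation, io, render, synthetic
from .aggregate import aggregate_extract, series_to_frame
from .types import (
    ChangePointTruth,
    CleaningConfig,
    ConsensusParams,
    VolunteerModel,
)

log = logging.getLogger("crowdcp")

STAGES = ["simulate", "aggregate", "render", "clean", "consensus", "evaluate", "tune"]


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artefact {path.name}: run the {produced_by!r} stage first"
        )
    return path


def load_config(path) -> dict:
    return io.load_yaml(path)


def _truths_from_config(config: dict) -> list[ChangePointTruth]:
    return [
        ChangePointTruth(
            series_id=t.get("series_id", "extract"),
            date=pd.Timestamp(t["date"]),
            kind=t["kind"],
            magnitude=float(t.get("magnitude", 5.0)),
            gap_days=int(t.get("gap_days", 14)),
            field_name=t.get("field_name"),
        )
        for t in config.get("truths", [])
    ]


def run_pipeline(
    config: dict,
    workdir,
    stages: Optional[Sequence[str]] = None,
    seed: Optional[int] = None,
) -> dict:
    """Run a prefix of the stage chain; returns the manifest."""
    if stages is None:
        stages = STAGES
    order = [STAGES.index(s) for s in stages]
    if sorted(order) != list(range(len(order))) or order != sorted(order):
        raise PipelineError(
            f"stages must be a prefix of {STAGES}, got {list(stages)}"
        )
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "config": config, "stages": {}}

    fields = io.fieldspecs_from_yaml(config["fields"])
    truths = _truths_from_config(config)
    granularities = config.get("granularities", ["day"])
    cutoff = float(config.get("cutoff_px", evaluation.DEFAULT_CUTOFF_PX))
    intervals = int(
        config.get("intervals_per_image", evaluation.DEFAULT_INTERVALS_PER_IMAGE)
    )
    cleaning_cfg = CleaningConfig(min_distance_cutoff_px=cutoff)
    params = ConsensusParams(**config.get("consensus_params", {}))
    model = VolunteerModel(**config.get("volunteer_model", {}))

    for stage in stages:
        arts: dict[str, str] = {}
        if stage == "simulate":
            records = synthetic.generate_extract(
                fields,
                tuple(config["date_span"]),
                truths,
                seed=seed,
                records_per_day=float(config.get("records_per_day", 50.0)),
                missing_rate=float(config.get("missing_rate", 0.05)),
            )
            io.write_records(records, workdir / "records.csv")
            io.write_truths(truths, workdir / "truths.csv")
            arts = {"records": "records.csv", "truths": "truths.csv"}
        elif stage == "aggregate":
            records = io.read_records(_require(workdir / "records.csv", "simulate"))
            series = aggregate_extract(
                records, fields,
                extract_id=config.get("extract_id", "extract"),
                granularities=granularities,
                subcategory_limit=int(config.get("subcategory_limit", 20)),
            )
            frame = series_to_frame(series)
            frame.to_csv(workdir / "series.csv", index=False, na_rep="")
            arts = {"series": "series.csv"}
        elif stage == "render":
            _require(workdir / "series.csv", "aggregate")
            arts = _render_stage(
                config, workdir, fields, truths, granularities, model, seed
            )
        elif stage == "clean":
            raw = io.read_lines(_require(workdir / "lines_raw.csv", "render"))
            first = cleaning.keep_first_attempts(raw, cleaning_cfg)
            merged = cleaning.merge_same_person(first, cleaning_cfg)
            log.info(
                "cleaning: %d lines in, %d after first-attempt filter, %d after merge",
                len(raw), len(first), len(merged),
            )
            io.write_lines(first, workdir / "lines_first.csv")
            io.write_lines(merged, workdir / "lines_clean.csv")
            arts = {"first_attempts": "lines_first.csv", "clean": "lines_clean.csv"}
        elif stage == "consensus":
            lines = io.read_lines(_require(workdir / "lines_clean.csv", "clean"))
            coords = render.manifest_to_coords(
                pd.read_csv(_require(workdir / "manifest.csv", "render"))
            )
            labels = consensus.consensus_labels(lines, params, coords)
            io.write_labels(labels, workdir / "labels.csv")
            arts = {"labels": "labels.csv"}
        elif stage == "evaluate":
            labels = io.read_labels(_require(workdir / "labels.csv", "consensus"))
            expert = io.read_lines(_require(workdir / "expert.csv", "render"))
            manifest_df = pd.read_csv(_require(workdir / "manifest.csv", "render"))
            counts = evaluation.match_labels(
                labels, expert, cutoff_px=cutoff, intervals_per_image=intervals,
                image_ids=manifest_df["image_id"].astype(str).tolist(),
            )
            m = evaluation.metrics(counts)
            payload = {
                "counts": {"tp": counts.tp, "tn": counts.tn,
                           "fp": counts.fp, "fn": counts.fn},
                "metrics": {
                    "sensitivity": m.sensitivity, "specificity": m.specificity,
                    "ppv": m.ppv, "npv": m.npv, "mcc": m.mcc,
                },
                "ci_95": m.ci_95,
            }
            (workdir / "metrics.json").write_text(
                json.dumps(payload, indent=2) + "\n"
            )
            arts = {"metrics": "metrics.json"}
        elif stage == "tune":
            lines = io.read_lines(_require(workdir / "lines_clean.csv", "clean"))
            expert = io.read_lines(_require(workdir / "expert.csv", "render"))
            manifest_df = pd.read_csv(_require(workdir / "manifest.csv", "render"))
            grid = evaluation.tune_grid(
                lines, expert,
                image_ids=manifest_df["image_id"].astype(str).tolist(),
                cutoff_px=cutoff, intervals_per_image=intervals,
            )
            grid.to_csv(workdir / "grid.csv", index=False)
            arts = {"grid": "grid.csv"}
        manifest["stages"][stage] = {
            "artefacts": arts,
            "sha256": {name: _sha256(workdir / fn) for name, fn in arts.items()},
        }
        log.info("stage %s complete: %s", stage, sorted(arts.values()))

    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _render_stage(config, workdir, fields, truths, granularities, model, seed):
    """Render a subset of series and simulate annotation lines on them."""
    frame = pd.read_csv(workdir / "series.csv")
    wanted = config.get("render_functions", ["n", "mean"])
    sel = frame[
        (frame["granularity"] == granularities[0])
        & (frame["function"].isin(wanted))
        & (frame["subcategory"].isna())
    ]
    entries: dict[str, render.PlotCoordinates] = {}
    all_lines, all_expert = [], []
    img_dir = workdir / "images"
    img_dir.mkdir(exist_ok=True)
    draw = bool(config.get("render_png", True))
    for i, ((field, function), grp) in enumerate(
        sorted(sel.groupby(["field", "function"]), key=lambda kv: kv[0])
    ):
        idx = pd.PeriodIndex(
            pd.DatetimeIndex(grp["timepoint"]), freq="D"
        )
        from .types import TimeSeries

        ts = TimeSeries(
            extract_id=config.get("extract_id", "extract"),
            field_name=field, function_label=function,
            granularity=granularities[0],
            points=pd.Series(grp["value"].to_numpy(dtype=float), index=idx),
        )
        coords = render.PlotCoordinates.for_series(ts)
        if draw:
            render.render(ts, img_dir / f"{ts.key}.png", coords=coords)
        entries[ts.key] = coords
        all_lines.append(
            synthetic.simulate_annotations(
                truths, coords, model, seed=seed + 17 * i + 1, image_id=ts.key
            )
        )
        all_expert.append(
            synthetic.simulate_expert(
                truths, coords, seed=seed + 17 * i + 2, image_id=ts.key,
            )
        )
    lines = pd.concat(all_lines, ignore_index=True) if all_lines else pd.DataFrame(
        columns=io.LINE_COLUMNS
    )
    expert = pd.concat(all_expert, ignore_index=True) if all_expert else pd.DataFrame(
        columns=io.LINE_COLUMNS
    )
    render.manifest_frame(entries).to_csv(workdir / "manifest.csv", index=False)
    io.write_lines(lines, workdir / "lines_raw.csv")
    io.write_lines(expert, workdir / "expert.csv")
    return {
        "manifest": "manifest.csv",
        "raw_lines": "lines_raw.csv",
        "expert": "expert.csv",
    }
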
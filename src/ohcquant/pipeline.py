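"""End-to-end pipeline: simulate → quantify → compare.

Runs the whole analysis on synthetic data with known truth: generates a
nuclear-position cohort, single-cell image stacks for recruitment, and
cisternae profiles; quantifies positions, recruitment indices and gap
lengths; and applies the cohort statistics (onset analysis across ages,
Kruskal–Wallis/Dunn across recruitment groups, Mann–Whitney on gaps).
All stage outputs are CSV/JSON written under one results directory with a
run manifest; given a fixed seed the outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .axis import batch_positions
from .cisternae import compare_gap_groups, gap_lengths, profiles_to_frame
from .config import PipelineConfig
from .io import write_stack
from .recruitment import batch_recruitment
from .stats import kruskal_dunn, onset_analysis
from .synthetic import (
    SyntheticCellSpec,
    generate_cell_image,
    generate_cisternae_cohort,
    generate_cohort,
    onset_cohort_spec,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

_FLOAT_FORMAT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return len(df)


def _log_event(handle, stage: str, **fields) -> None:
    handle.write(json.dumps({"stage": stage, **fields}, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute all stages under ``out_dir`` and return the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    row_counts: dict[str, int] = {}

    with open(out / "log.jsonl", "w") as log:
        # ---- stage 1: simulate -------------------------------------------
        cohort_spec = onset_cohort_spec(
            n_per_group=config.cohort.n_per_group,
            ages=config.cohort.ages,
            onset_age=config.cohort.onset_age,
            baseline=config.cohort.baseline,
            delta=config.cohort.delta,
            control_sd=config.cohort.control_sd,
            mutant_sd=config.cohort.mutant_sd,
            seed=config.seed,
        )
        cohort, cohort_truth = generate_cohort(cohort_spec)
        # express each drawn position as a straight-cell landmark triple so
        # the quantification stage genuinely runs the axis morphometry
        length = 30.0
        landmarks = cohort.assign(
            ax=0.0, ay=0.0, az=0.0,
            nx=cohort["relative_position"] * length, ny=0.0, nz=0.0,
            bx=length, by=0.0, bz=0.0,
            units="um", voxel_z=np.nan, voxel_y=np.nan, voxel_x=np.nan,
        ).drop(columns=["relative_position"])
        row_counts["landmarks"] = _write_csv(landmarks, out / "landmarks.csv")
        row_counts["cohort_truth"] = _write_csv(cohort, out / "cohort_truth.csv")
        _log_event(log, "simulate", table="landmarks", rows=len(landmarks))

        image_triples = []
        rng_seeds = np.random.SeedSequence(config.seed).generate_state(10_000)
        i = 0
        for group, k in sorted(config.recruitment.enrichment.items()):
            for c in range(config.recruitment.n_per_group):
                spec = SyntheticCellSpec(
                    cell_length=config.recruitment.cell_length,
                    axis_curvature=config.recruitment.axis_curvature,
                    ne_enrichment_factor=k,
                )
                seed_i = int(rng_seeds[i] % (2**31)); i += 1
                stack, _ = generate_cell_image(spec, seed=seed_i)
                cell_id = f"{group}_cell{c:02d}"
                if config.write_images:
                    write_stack(stack, out / f"{cell_id}.tif")
                image_triples.append((cell_id, group, stack))
        _log_event(log, "simulate", table="images", rows=len(image_triples))

        profiles = generate_cisternae_cohort(
            {g: {"mean_gap": m, "sd_gap": config.cisternae.sd_gap}
             for g, m in config.cisternae.mean_gap.items()},
            seed=config.seed,
            n_cells_per_group=config.cisternae.n_cells_per_group,
            segments_per_cell=config.cisternae.segments_per_cell,
            segment_length=config.cisternae.segment_length,
        )
        row_counts["profiles"] = _write_csv(
            profiles_to_frame(profiles), out / "profiles.csv"
        )
        _log_event(log, "simulate", table="profiles", rows=row_counts["profiles"])

        # ---- stage 2: quantify -------------------------------------------
        positions = batch_positions(landmarks)
        row_counts["positions"] = _write_csv(positions, out / "positions.csv")
        n_failed = int((positions["error"] != "").sum())
        _log_event(log, "quantify", table="positions",
                   rows=len(positions), failed=n_failed)

        recruit = batch_recruitment(
            image_triples, band_width=config.band_width,
            method=config.threshold_method,
        )
        row_counts["recruitment"] = _write_csv(recruit, out / "recruitment.csv")
        _log_event(log, "quantify", table="recruitment", rows=len(recruit))

        gap_rows = []
        for p in profiles:
            gs = gap_lengths(p)
            for j, g in enumerate(gs.gaps):
                gap_rows.append(
                    {"cell_id": p.cell_id, "group": p.group,
                     "gap_index": j, "gap_um": g}
                )
        gaps_df = pd.DataFrame(gap_rows)
        per_cell = (
            gaps_df.groupby(["cell_id", "group"], sort=False)["gap_um"]
            .mean().reset_index().rename(columns={"gap_um": "mean_gap_um"})
        )
        row_counts["gaps"] = _write_csv(gaps_df, out / "gaps.csv")
        row_counts["gap_cell_means"] = _write_csv(per_cell, out / "gap_cell_means.csv")
        _log_event(log, "quantify", table="gaps", rows=len(gaps_df))

        # ---- stage 3: compare --------------------------------------------
        onset_table, onset_age = onset_analysis(
            positions.dropna(subset=["relative_position"]),
            value="relative_position", age="age", group="group", q=config.q,
        )
        row_counts["onset"] = _write_csv(onset_table, out / "onset.csv")
        _log_event(log, "compare", table="onset",
                   onset_age=None if onset_age is None else str(onset_age))

        recruit_groups = {
            g: sub["recruitment_index"].dropna().to_numpy()
            for g, sub in recruit.groupby("group", sort=True)
        }
        if len(recruit_groups) >= 3:
            kd = kruskal_dunn(recruit_groups)
            stats_payload = {
                "test": kd.name, "H": kd.statistic, "p": kd.pvalue,
                "pairwise": kd.comparisons.to_dict(orient="records"),
            }
        else:
            stats_payload = {
                "test": "group-summaries-only",
                "groups": {g: float(np.mean(v)) for g, v in recruit_groups.items()},
            }
        (out / "recruitment_stats.json").write_text(
            json.dumps(stats_payload, sort_keys=True, indent=2, default=float)
        )

        gap_cmp = compare_gap_groups(
            {g: [p for p in profiles if p.group == g]
             for g in config.cisternae.mean_gap}
        )
        row_counts["gap_summary"] = _write_csv(
            gap_cmp["summary"], out / "gap_summary.csv"
        )
        (out / "gap_comparison.json").write_text(
            json.dumps(
                {"test": gap_cmp["test"].name, "U": gap_cmp["test"].statistic,
                 "p": gap_cmp["test"].pvalue,
                 "method": gap_cmp["test"].details["method"]},
                sort_keys=True, indent=2,
            )
        )
        _log_event(log, "compare", table="gaps", p=gap_cmp["test"].pvalue)

    manifest = {
        "package": "ohcquant",
        "version": __version__,
        "config": json.loads(config.model_dump_json()),
        "config_hash": config.content_hash(),
        "row_counts": row_counts,
        "elapsed_s": round(time.time() - t0, 2),
    }
    # elapsed time is excluded from determinism guarantees; everything else is
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=2))
    return out
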
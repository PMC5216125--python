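"""End-to-end pipeline: simulate -> stereology -> membrane statistics.

Stage seeds are derived deterministically from the single global seed via
``numpy.random.SeedSequence(seed).spawn``, giving each stage an independent
stream; identical config + seed therefore produce byte-identical outputs.
Each synthetic field plays the role of one micrograph; fields are grouped
into ``n_fields`` independent experiments for the density s.e.m. (one
field per experiment by default, mirroring replicate experiments).
"""

from __future__ import annotations

import datetime
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import MitosomeProfile, Point2D
from .io import (
    DENSITIES_SCHEMA,
    DISTANCES_SCHEMA,
    POINTS_SCHEMA,
    PROFILES_SCHEMA,
    RunConfig,
    RunManifest,
    write_report,
    write_table,
)
from .membrane import LocalizationComparison, measure_distances
from .stereology import (
    AreaEstimate,
    LabelingDensity,
    gold_density,
    overlay_grid,
    point_count_area,
    summarize_densities,
)
from .synthetic import (
    DEFAULT_GOLD_COUNTS,
    FieldConfig,
    GoldPlacementLaw,
    generate_field,
    generate_gold,
    matched_random_points,
)

__all__ = ["run_pipeline", "profiles_to_table", "profiles_from_table"]

log = logging.getLogger("mitogold")


def profiles_to_table(profiles: list[MitosomeProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            profile_id=[p.profile_id for p in profiles],
            field_id=[p.field_id for p in profiles],
            cx_nm=[p.center.x for p in profiles],
            cy_nm=[p.center.y for p in profiles],
            semi_major_nm=[p.semi_major_outer for p in profiles],
            semi_minor_nm=[p.semi_minor_outer for p in profiles],
            theta_rad=[p.orientation for p in profiles],
            membrane_inset_nm=[p.membrane_inset for p in profiles],
        )
    )


def profiles_from_table(df: pd.DataFrame) -> list[MitosomeProfile]:
    return [
        MitosomeProfile(
            profile_id=str(r.profile_id),
            field_id=str(r.field_id),
            center=Point2D(float(r.cx_nm), float(r.cy_nm)),
            semi_major_outer=float(r.semi_major_nm),
            semi_minor_outer=float(r.semi_minor_nm),
            orientation=float(r.theta_rad),
            membrane_inset=float(r.membrane_inset_nm),
        )
        for r in df.itertuples(index=False)
    ]


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute simulate -> stereology -> membrane-stats and write outputs.

    Writes profiles.csv, gold.csv, points.csv (matched random points),
    densities.csv, summary.csv, distances.csv, report.json and
    manifest.json under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(config.rng_seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in root_seq.spawn(4)]
    t0 = time.perf_counter()

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        counts = config.counts_per_label or dict(DEFAULT_GOLD_COUNTS)
        field_cfg = FieldConfig(
            n_fields=config.n_fields,
            profiles_per_field=config.profiles_per_field,
            membrane_inset=config.membrane_inset_nm,
            rng_seed=stage_seeds[0],
        )
        rng = np.random.default_rng(stage_seeds[0])
        profiles: list[MitosomeProfile] = []
        compartments = {}
        for k in range(field_cfg.n_fields):
            fid = f"F{k}"
            p, c = generate_field(field_cfg, field_id=fid, rng=rng)
            profiles.extend(p)
            compartments[fid] = c
        law = GoldPlacementLaw(
            law=config.gold_law, scale_nm=config.gold_scale_nm, counts_per_label=counts
        )
        gold = generate_gold(profiles, law, seed=stage_seeds[1])
        rand = matched_random_points(gold, profiles, seed=stage_seeds[2])
        write_table(profiles_to_table(profiles), out / "profiles.csv", PROFILES_SCHEMA)
        write_table(gold, out / "gold.csv", POINTS_SCHEMA)
        write_table(rand, out / "points.csv", POINTS_SCHEMA)
        log.info(
            "simulate: %d profiles over %d fields, %d gold, %d random points",
            len(profiles), field_cfg.n_fields, len(gold), len(rand),
        )
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageFailure(stage, e) from e

    # --- stereology -------------------------------------------------------
    stage = "stereology"
    try:
        grid_rng = np.random.default_rng(stage_seeds[3])
        densities: list[LabelingDensity] = []
        by_field = {fid: [p for p in profiles if p.field_id == fid] for fid in compartments}
        for k, (fid, comps) in enumerate(sorted(compartments.items())):
            exp_id = f"E{k}"  # one field per experiment
            field_gold = gold[gold["field_id"] == fid]
            # mitosome compartment: pooled profile area at the fine spacing
            hits = 0
            for prof in by_field[fid]:
                a = prof.semi_major_outer
                cx, cy = prof.center.x, prof.center.y
                grid = overlay_grid(
                    (cx - a, cy - a, cx + a, cy + a),
                    config.grid_spacing_mitosome_nm,
                    grid_rng,
                )
                hits += point_count_area(prof, grid).hits
            area = AreaEstimate(
                hits=hits, spacing=config.grid_spacing_mitosome_nm, compartment="mitosome"
            )
            for label in sorted(field_gold["label"].unique()):
                densities.append(
                    gold_density(field_gold, area, label, "mitosome", exp_id)
                )
            # cytoplasm / nucleus at the coarse spacing (no gold there under
            # the default intra-mitosome placement laws; densities are 0)
            for comp_name in ("cytoplasm", "nucleus"):
                geom = comps[comp_name]
                grid = overlay_grid(
                    geom.bounds, config.grid_spacing_cyto_nucleus_nm, grid_rng
                )
                est = point_count_area(geom, grid, comp_name)
                if est.hits == 0:
                    continue
                for label in sorted(field_gold["label"].unique()):
                    off_profile = field_gold[field_gold["profile_id"] == ""]
                    densities.append(
                        gold_density(off_profile, est, label, comp_name, exp_id)
                    )
        dens_df = pd.DataFrame(
            dict(
                label=[d.label for d in densities],
                compartment=[d.compartment for d in densities],
                experiment_id=[d.experiment_id for d in densities],
                gold_count=[d.gold_count for d in densities],
                area_um2=[d.area_um2 for d in densities],
                density_per_um2=[d.density_per_um2 for d in densities],
            )
        )
        write_table(dens_df, out / "densities.csv", DENSITIES_SCHEMA)
        summary = summarize_densities(densities)
        summary[["label", "compartment", "mean", "sem", "n"]].to_csv(
            out / "summary.csv", index=False
        )
        log.info("stereology: %d density records", len(densities))
    except Exception as e:  # noqa: BLE001
        raise StageFailure(stage, e) from e

    # --- membrane statistics ---------------------------------------------
    stage = "membrane-stats"
    try:
        gold_d = measure_distances(gold, profiles)
        rand_d = measure_distances(rand, profiles)
        dist_rows = pd.concat([gold_d, rand_d], ignore_index=True)
        dist_rows = dist_rows[["point_id", "label", "kind", "profile_id", "distance_nm"]]
        write_table(dist_rows, out / "distances.csv", DISTANCES_SCHEMA)
        model = LocalizationComparison(
            gold_d,
            rand_d,
            bin_edges=config.bin_edges_nm,
            band_width=config.band_width_nm,
        )
        results = model.fit()
        write_report(results.to_dict(), out / "report.json")
        log.info(
            "membrane-stats: pooled n=%d, band inside fraction %.3f (gold) vs %.3f (random)",
            results.pooled_gold.n,
            results.pooled_band_gold.fraction_inside,
            results.pooled_band_random.fraction_inside,
        )
    except Exception as e:  # noqa: BLE001
        raise StageFailure(stage, e) from e

    manifest = RunManifest(
        tool_version=__version__,
        config_hash=config.config_hash(),
        input_hashes={},
        seed=config.rng_seed,
        timestamp_utc=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    write_report(manifest.to_dict(), out / "manifest.json")
    log.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return manifest
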
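"""End-to-end pipeline: gridding through hotspots, gaps, and SHA overlays."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .asciigrid import read_ascii_grid
from .grid import make_grid
from .occurrences import GROUPS, build_incidence, read_catalog, read_occurrences
from .pattern_stats import correlogram, pattern_vector
from .prioritization import (
    greedy_complementarity,
    group_richness,
    integrate_hotspots,
    top_complementarity_hotspots,
    top_richness_hotspots,
)
from .reserves import covered_cells, coverage_report, gap_analysis, read_reserves
from .suitability import SuitabilityStack, hotspot_sha_overlap, overlay_classes, threshold_and_superpose

logger = logging.getLogger("priorigrid")

STAGES = (
    "gridding", "richness", "complementarity", "integration",
    "correlogram", "gaps", "sha",
)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run; echoed into the manifest."""

    catalog: str
    occurrences: str
    out_dir: str
    reserves: str | None = None
    suitability_dir: str | None = None
    extent: tuple[float, float, float, float] = (100.0, 20.0, 110.0, 30.0)
    resolution: float = 0.5
    fraction: float = 0.05
    k_override: int | None = None
    k_total: int = 150
    greedy_criterion: str = "all_species"
    tau: float = 0.75
    n_min: int = 5
    subcell_rule: str = "all"
    coverage_rule: str = "intersects"
    seed: int = 0


def _load_stack(scenario_dir: Path, scenario: str, tau: float) -> SuitabilityStack | None:
    files = sorted(scenario_dir.glob("*.asc"))
    if not files:
        return None
    rasters = {f.stem: read_ascii_grid(f) for f in files}
    return SuitabilityStack(scenario, rasters, tau)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write outputs under ``out_dir``, return the manifest.

    Stage failures abort with the stage name in the exception; optional
    inputs (reserves, suitability rasters) that are absent skip their stage
    with an explicit notice in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    stage = "gridding"
    try:
        grid = make_grid(config.extent, config.resolution)
        catalog = read_catalog(config.catalog)
        occ = read_occurrences(config.occurrences, catalog, grid)
        incidence = build_incidence(occ, grid)
        manifest["stages"][stage] = {
            "status": "completed",
            "n_cells": grid.n_cells,
            "n_species_catalog": len(catalog),
            "group_totals": catalog.group_totals(),
            "occurrence_counters": occ.counters,
            "n_occupied_cells": int(incidence.n_occupied),
        }

        stage = "richness"
        pattern = group_richness(incidence, catalog)
        rank_r = top_richness_hotspots(pattern, config.fraction, config.k_override)
        rank_r.to_frame().to_csv(out / "richness_ranking.csv", index=False)
        pattern.table.to_csv(out / "richness_pattern.csv")
        manifest["stages"][stage] = {
            "status": "completed",
            "k": rank_r.k,
            "n_selected": len(rank_r),
            "tie_extended": rank_r.tie_extended,
        }

        stage = "complementarity"
        solution = greedy_complementarity(incidence, catalog, config.greedy_criterion)
        rank_c = top_complementarity_hotspots(solution, rank_r.k)
        rank_c.to_frame().to_csv(out / "complementarity_ranking.csv", index=False)
        manifest["stages"][stage] = {
            "status": "completed",
            "n_steps": len(solution.steps),
            "total_gain": solution.total_gain(),
            "n_selected": len(rank_c),
            "tie_extended": rank_c.tie_extended,
        }

        stage = "integration"
        final = integrate_hotspots(rank_r, rank_c, config.k_total)
        final.to_frame().to_csv(out / "final_hotspots.csv", index=False)
        classes = {c: {"hotspot_class": "first"} for c in final.first_class}
        classes.update({c: {"hotspot_class": "second"} for c in final.second_class})
        grid.write_geojson(out / "final_hotspots.geojson", sorted(final.cells), classes)
        manifest["stages"][stage] = {
            "status": "completed",
            "n_first_class": len(final.first_class),
            "n_second_class": len(final.second_class),
        }

        stage = "correlogram"
        vectors = [pattern_vector(pattern, g, grid) for g in GROUPS]
        vectors += [pattern_vector(solution, g, grid) for g in GROUPS]
        kept = [v for v in vectors if v.values.std() > 0]
        dropped = [v.label for v in vectors if v.values.std() == 0]
        if len(kept) >= 2:
            report = correlogram(kept)
            report.to_csv(out / "correlogram_wide.csv", form="wide")
            report.to_csv(out / "correlogram_long.csv", form="long")
            manifest["stages"][stage] = {
                "status": "completed",
                "n_patterns": len(kept),
                "dropped_constant_patterns": dropped,
            }
        else:
            manifest["stages"][stage] = {
                "status": "skipped",
                "notice": "fewer than 2 non-constant patterns",
            }

        stage = "gaps"
        if config.reserves and Path(config.reserves).exists():
            reserve_set = read_reserves(config.reserves)
            covers = {
                "national": covered_cells(grid, reserve_set, ("national",),
                                          config.coverage_rule) if reserve_set.by_tier("national") else set(),
                "provincial": covered_cells(grid, reserve_set, ("provincial",),
                                            config.coverage_rule) if reserve_set.by_tier("provincial") else set(),
            }
            covers["union"] = covers["national"] | covers["provincial"]
            protected, gaps = gap_analysis(final, covers["union"])
            report_cov = coverage_report(
                incidence, catalog, final, covers,
                rankings={"richness": set(rank_r.cell_ids),
                          "complementarity": set(rank_c.cell_ids)},
            )
            report_cov.to_csv(out / "coverage_table.csv")
            grid.write_geojson(out / "gap_cells.geojson", gaps)
            manifest["stages"][stage] = {
                "status": "completed",
                "n_reserves": len(reserve_set),
                "n_protected_hotspots": len(protected),
                "n_gap_hotspots": len(gaps),
            }
        else:
            covers = None
            gaps = None
            manifest["stages"][stage] = {
                "status": "skipped",
                "notice": "no reserve file supplied; gap analysis skipped",
            }

        stage = "sha"
        sha_dir = Path(config.suitability_dir) if config.suitability_dir else None
        if sha_dir and sha_dir.exists():
            cur = _load_stack(sha_dir / "current", "current", config.tau)
            fut = _load_stack(sha_dir / "future", "future", config.tau)
            if cur is None or fut is None:
                manifest["stages"][stage] = {
                    "status": "skipped",
                    "notice": "suitability directory lacks current/ or future/ rasters",
                }
            else:
                v_cur, m_cur = threshold_and_superpose(cur)
                v_fut, m_fut = threshold_and_superpose(fut)
                rule = config.subcell_rule
                if rule.startswith("fraction:"):
                    rule = float(rule.split(":", 1)[1])
                overlap = hotspot_sha_overlap(
                    sorted(final.cells), {"current": m_cur, "future": m_fut},
                    grid, cur.reference, rule,
                )
                overlap.classes.to_csv(out / "sha_overlap.csv")
                from .asciigrid import write_ascii_grid

                write_ascii_grid(v_cur, out / "superposed_current.asc")
                write_ascii_grid(v_fut, out / "superposed_future.asc")
                sets = {}
                if covers is not None:
                    sets = {"gaps_nnr_pnr": set(gaps),
                            "covered_nnr_pnr": final.cells - set(gaps)}
                if sets:
                    overlay_classes(overlap, sets).to_csv(
                        out / "sha_stability_overlay.csv", index=False
                    )
                manifest["stages"][stage] = {
                    "status": "completed",
                    "n_modeled_species": len(cur),
                    "current": overlap.counts("current"),
                    "future": overlap.counts("future"),
                    "n_stable_hotspots": len(overlap.stable_cells),
                }
        else:
            manifest["stages"][stage] = {
                "status": "skipped",
                "notice": "no suitability rasters supplied; SHA stage skipped",
            }
    except Exception as exc:
        manifest["stages"].setdefault(stage, {})
        manifest["stages"][stage].update({"status": "failed", "error": str(exc)})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["completed_stages"] = sum(
        1 for s in manifest["stages"].values() if s["status"] == "completed"
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
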
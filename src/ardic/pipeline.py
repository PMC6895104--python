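"""End-to-end analysis: AR-DIC -> kinematics -> metrics -> region trees.

This is the integrated run behind the ``ardic analyze`` command; every
artifact it writes is a stable text format (CSV/JSON) plus rendered PNG
heat maps, and the JSON manifest records every resolved parameter so a
rerun reproduces the outputs exactly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adaptive import ARConfig, ReferenceTrace, refine_tadapt, run_ardic
from .io import ImageStack, write_fields, write_manifest
from .kinematics import principal_strains, strain_fields, velocity_series
from .metrics import (
    ContractionCriteria,
    NORM_BLOCK_AREA_UM2,
    beating_area,
    bpm_fft,
    bpm_peaks,
    compare_cv_groups,
    contraction_mask,
    cv_series,
    cv_split,
    displacement_signal,
    heatmaps,
)
from .piv import DEFAULT_SCHEDULE
from .tree import asc_map, astc_table, build_forest, find_origins, origin_lags

log = logging.getLogger(__name__)

__all__ = ["AnalysisResult", "analyze_stack", "write_results", "validate_fields"]


@dataclass
class AnalysisResult:
    """Everything the integrated pipeline computes for one video."""

    fields: list
    trace: ReferenceTrace
    t_adapt: float
    refinement_history: list
    velocity: list
    strains: list
    signal: np.ndarray
    bpm_fft: object
    bpm_peaks: float | None
    max_displacement_um: float
    beating_area_um2: np.ndarray
    coverage_pct: np.ndarray
    cv: np.ndarray
    cv_high: np.ndarray
    cv_cutoff: float
    frequency_map: np.ndarray
    magnitude_map: np.ndarray
    forest: object
    origins: list
    singletons: list
    group_comparison: pd.DataFrame
    params: dict = dc_field(default_factory=dict)


def analyze_stack(
    stack: ImageStack,
    t_adapt: float,
    criteria: ContractionCriteria | None = None,
    schedule=None,
    refine: bool = False,
    initial_reference_index: int = 0,
    refine_step: float = 0.1,
    drift_tolerance: float = 0.1,
    norm_area_um2: float = NORM_BLOCK_AREA_UM2,
    smooth_strain_sigma_cells: float = 0.0,
) -> AnalysisResult:
    """Run the full spatiotemporal contraction analysis of one stack."""
    criteria = criteria or ContractionCriteria()
    schedule = tuple(schedule) if schedule is not None else DEFAULT_SCHEDULE
    cfg = ARConfig(
        t_adapt=t_adapt,
        initial_reference_index=initial_reference_index,
        refine=refine,
        refine_step=refine_step,
        drift_tolerance=drift_tolerance,
    )
    history: list = []
    if refine:
        t_final, trace, history = refine_tadapt(stack, cfg, schedule)
        cfg.t_adapt = t_final
        fields, trace = run_ardic(stack, cfg, schedule)
    else:
        t_final = t_adapt
        fields, trace = run_ardic(stack, cfg, schedule)

    px = stack.pixel_size_um
    spacing = schedule[-1].grid_spacing_px if hasattr(schedule[-1], "grid_spacing_px") else schedule[-1][2]
    block_area = (spacing * px) ** 2

    vel = velocity_series(fields, stack.fps, px)
    strains = [strain_fields(f, smooth_strain_sigma_cells) for f in fields]

    sig = displacement_signal(fields, px, criteria.threshold_um)
    est_fft = bpm_fft(sig, stack.fps)
    est_peaks = bpm_peaks(sig, stack.fps) if np.isfinite(sig).any() else None

    masks = [contraction_mask(f, px, criteria.threshold_um) for f in fields]
    areas, coverages = [], []
    for f, m in zip(fields, masks):
        a, c = beating_area(m, block_area, n_valid=int(f.valid.sum()))
        areas.append(a)
        coverages.append(c)
    cv = cv_series(fields, px, criteria.threshold_um, block_area, norm_area_um2)
    cv_high, cutoff = cv_split(cv)
    freq_map, mag_map = heatmaps(fields, px, criteria.threshold_um)
    max_disp = max(
        (float(np.max(f.magnitude_um(px)[f.valid])) for f in fields
         if f.valid.any()),
        default=0.0,
    )

    gx = fields[0].grid_x if fields else np.array([])
    gy = fields[0].grid_y if fields else np.array([])
    masks_by_frame = {f.frame_index: m for f, m in zip(fields, masks)}
    forest = build_forest(
        masks_by_frame, block_area, criteria.min_region_area_um2, gx, gy, px,
        stack.fps,
    )
    origins, singletons = find_origins(forest)

    max_speed = np.array([float(v.speed[v.valid].max()) if v.valid.any() else 0.0
                          for v in vel])
    e1_max, e2_min = [], []
    for s in strains:
        e1, e2, _ = principal_strains(s)
        ok = s.valid
        e1_max.append(float(e1[ok].max()) if ok.any() else 0.0)
        e2_min.append(float(e2[ok].min()) if ok.any() else 0.0)
    # velocities exist from the second analysed frame on; align labels
    comparison = compare_cv_groups(
        max_speed, np.array(e1_max)[1:], np.array(e2_min)[1:], cv_high[1:]
    )

    params = {
        "fps": stack.fps,
        "pixel_size_um": px,
        "t_adapt": t_final,
        "refined": bool(refine),
        "refine_step": refine_step,
        "drift_tolerance": drift_tolerance,
        "threshold_um": criteria.threshold_um,
        "alt_thresholds_um": list(criteria.alt_thresholds_um),
        "min_region_area_um2": criteria.min_region_area_um2,
        "norm_area_um2": norm_area_um2,
        "block_area_um2": block_area,
        "schedule": [
            [p.window_px, p.search_px, p.grid_spacing_px] for p in schedule
        ],
        "initial_reference_index": initial_reference_index,
        "version": __version__,
    }
    return AnalysisResult(
        fields=fields,
        trace=trace,
        t_adapt=t_final,
        refinement_history=history,
        velocity=vel,
        strains=strains,
        signal=sig,
        bpm_fft=est_fft,
        bpm_peaks=est_peaks,
        max_displacement_um=max_disp,
        beating_area_um2=np.array(areas),
        coverage_pct=np.array(coverages),
        cv=cv,
        cv_high=cv_high,
        cv_cutoff=cutoff,
        frequency_map=freq_map,
        magnitude_map=mag_map,
        forest=forest,
        origins=origins,
        singletons=singletons,
        group_comparison=comparison,
        params=params,
    )


def _grid_csv(path: Path, grid_x, grid_y, values) -> None:
    gx, gy = np.meshgrid(grid_x, grid_y)
    pd.DataFrame(
        {"grid_x": gx.ravel(), "grid_y": gy.ravel(), "value": values.ravel()}
    ).to_csv(path, index=False, float_format="%.6f")


def _render_map(path: Path, values, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(values, origin="upper", cmap="viridis")
    fig.colorbar(im, ax=ax)
    ax.set_title(title)
    ax.set_xlabel("grid x")
    ax.set_ylabel("grid y")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_results(result: AnalysisResult, out_dir: str | Path,
                  render_png: bool = True) -> Path:
    """Write the full artifact set of one analysis run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    write_fields(result.fields, out / "fields.csv")
    result.trace.to_frame().to_csv(out / "trace.csv", index=False,
                                   float_format="%.6f")

    frames = [f.frame_index for f in result.fields]
    pd.DataFrame(
        {
            "frame": frames,
            "beating_area_um2": result.beating_area_um2,
            "coverage_pct": result.coverage_pct,
            "cv": result.cv,
            "cv_label": np.where(result.cv_high, "high", "low"),
        }
    ).to_csv(out / "metrics.csv", index=False, float_format="%.6f")

    gx = result.fields[0].grid_x
    gy = result.fields[0].grid_y
    _grid_csv(out / "heatmap_frequency.csv", gx, gy, result.frequency_map)
    _grid_csv(out / "heatmap_magnitude.csv", gx, gy, result.magnitude_map)
    asc = asc_map(result.forest)
    _grid_csv(out / "asc_map.csv", gx, gy, asc)
    if render_png:
        _render_map(out / "heatmap_frequency.png", result.frequency_map,
                    "contraction frequency (fraction of frames)")
        _render_map(out / "heatmap_magnitude.png", result.magnitude_map,
                    "mean displacement (um)")
        _render_map(out / "asc_map.png", asc, "accumulated spatial contraction")

    nodes_df, edges_df = astc_table(result.forest)
    nodes_df.to_csv(out / "tree_nodes.csv", index=False, float_format="%.6f")
    edges_df.to_csv(out / "tree_edges.csv", index=False)
    _, lags = origin_lags(result.forest)
    lags.to_csv(out / "origin_lags.csv", index=False, float_format="%.6f")
    result.group_comparison.to_csv(out / "cv_groups.csv", index=False,
                                   float_format="%.6f")

    manifest = dict(result.params)
    manifest.update(
        {
            "bpm_fft": result.bpm_fft.bpm,
            "bpm_fft_prominence": result.bpm_fft.prominence,
            "bpm_fft_reliable": result.bpm_fft.reliable,
            "bpm_peaks": result.bpm_peaks,
            "max_displacement_um": result.max_displacement_um,
            "max_coverage_pct": float(np.max(result.coverage_pct))
            if len(result.coverage_pct)
            else 0.0,
            "cv_cutoff": result.cv_cutoff,
            "n_origins": len(result.origins),
            "n_singletons": len(result.singletons),
            "t_adapt_history": result.refinement_history,
            "n_reference_switches": int(result.trace.switches.sum()),
            "runtime_s": round(time.time() - t0, 3),
        }
    )
    write_manifest(manifest, out / "manifest.json")
    return out


def validate_fields(fields, truth, resolvable_mask=None) -> dict:
    """Compare measured fields against ground truth on the shared grid.

    Returns RMSE, mean bias per component, and worst-vector error over
    valid vectors (restricted to ``resolvable_mask`` columns if given).
    """
    errs_u, errs_v = [], []
    for f in fields:
        k = f.frame_index
        tu = truth.u_grid[k]
        tv = truth.v_grid[k]
        if tu.shape != f.u.shape:
            raise ValueError("measured and truth grids do not match")
        ok = f.valid.copy()
        if resolvable_mask is not None:
            ok &= np.broadcast_to(resolvable_mask, ok.shape)
        errs_u.append((f.u - tu)[ok])
        errs_v.append((f.v - tv)[ok])
    eu = np.concatenate(errs_u) if errs_u else np.array([0.0])
    ev = np.concatenate(errs_v) if errs_v else np.array([0.0])
    err2 = eu**2 + ev**2
    return {
        "rmse_px": float(np.sqrt(err2.mean())),
        "bias_u_px": float(eu.mean()),
        "bias_v_px": float(ev.mean()),
        "max_err_px": float(np.sqrt(err2.max())),
        "n_vectors": int(err2.size),
    }
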
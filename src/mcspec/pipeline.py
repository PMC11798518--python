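"""End-to-end orchestration of the three per-sample analyses.

``run_all`` renders (or loads) one scene, runs thickness inversion, the
per-pixel XRF map fits, thickness binning with the carbonate-dilution
trend, the XANES line scan, and the WAXS classification/refinement, and
writes a report bundle: CSV tables, TIFF/PNG maps with the 0.3/0.5/1 µm
interpretation contours, and a machine-readable JSON summary.  The run
is deterministic under a fixed seed; every decided default (matrix,
angles, Scherrer constant, escape fraction) is logged for provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mcio
from .phantom import (BACKGROUND, CORE, PERIPHERY, RIM, build_scene,
                      render_waxs, render_xanes, render_xrf_cube)
from .physics import get_matrix
from .waxs import (WHIT_PHASE, Profile1D, classify_profiles,
                   phase_peak_positions, refine_profile, synthesize_profile)
from .xanes import line_scan_lcf
from .xrf import (DetectorModel, GeometryModel, bin_by_thickness,
                  carbonate_dilution_model, effective_thickness_map, fit_cube,
                  rescale_trace_fractions)

__all__ = ["RunConfig", "run_all", "PipelineError"]

logger = logging.getLogger("mcspec")


class PipelineError(RuntimeError):
    """A stage failed; the bundle written so far is partial."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    preset: str = "benign"
    seed: int = 0
    out_dir: str = "mcspec_out"
    shape: tuple[int, int] = (48, 48)
    matrix: str = "HAP_B"
    energies_kev: tuple[float, ...] = (2.1, 2.5, 4.2)
    alpha_deg: float = 84.0
    beta_deg: float = 6.0
    mask_thresholds_um: tuple[float, float, float] = (0.3, 0.5, 1.0)
    bin_edges_um: tuple[float, ...] = (0.25, 0.5, 1.0, 1.75, 2.5, 3.25, 4.0, 5.0, 6.0)
    counts_scale: float = 5000.0
    waxs_components: int = 4

    def __post_init__(self) -> None:
        lo, mid, hi = self.mask_thresholds_um
        if not lo < mid < hi:
            raise ValueError("mask thresholds must be ordered")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a key=value text config."""
        kw = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if "=" not in s:
                raise ValueError(f"{path}: line {ln}: expected key=value")
            key, val = (t.strip() for t in s.split("=", 1))
            if key in ("seed", "waxs_components"):
                kw[key] = int(val)
            elif key in ("alpha_deg", "beta_deg", "counts_scale"):
                kw[key] = float(val)
            elif key in ("shape", "energies_kev", "mask_thresholds_um",
                         "bin_edges_um"):
                parts = tuple(float(v) for v in val.split(","))
                kw[key] = tuple(int(v) for v in parts) if key == "shape" else parts
            else:
                kw[key] = val
        return cls(**kw)


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle.

    Returns the summary dictionary (also written as summary.json).  On a
    stage failure the partial bundle remains on disk and
    :class:`PipelineError` carries the stage trace.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    det = DetectorModel()
    geom = GeometryModel(config.alpha_deg, config.beta_deg)
    matrix = get_matrix(config.matrix)
    summary: dict = {
        "preset": config.preset,
        "seed": config.seed,
        "defaults": {
            "matrix": config.matrix,
            "alpha_deg": config.alpha_deg,
            "beta_deg": config.beta_deg,
            "scherrer_k": WHIT_PHASE.scherrer_k,
            "escape_fraction": det.escape_fraction,
            "mask_thresholds_um": list(config.mask_thresholds_um),
        },
    }
    stage = "build_scene"
    try:
        scene = build_scene(config.preset, config.seed, config.shape)
        logger.info("scene %s built: %sx%s", config.preset, *config.shape)

        # --- thickness ---------------------------------------------------
        stage = "thickness"
        cubes = {e: render_xrf_cube(scene, e, det, geom,
                                    counts_scale=config.counts_scale)
                 for e in config.energies_kev}
        ref_cube = cubes[2.5] if 2.5 in cubes else next(iter(cubes.values()))
        thickness = effective_thickness_map(ref_cube, matrix)
        mcio.write_map_tiff(out / "thickness_um.tif", thickness.t_um)
        mcio.write_map_png(out / "thickness_um.png", thickness.t_um,
                           thickness.t_um, config.mask_thresholds_um,
                           title="effective thickness (um)")
        summary["thickness"] = {
            "median_core_um": float(np.median(
                thickness.t_um[scene.region_mask(CORE)])),
            "n_clipped": thickness.n_clipped,
        }

        # --- XRF maps ----------------------------------------------------
        stage = "xrf_maps"
        maps = {}
        for e, cube in cubes.items():
            maps[e] = fit_cube(cube, thickness, matrix, det, geom,
                               mask_threshold_um=config.mask_thresholds_um[1])
            for el, arr in maps[e].fractions.items():
                mcio.write_map_tiff(out / f"w_{el}_{e:g}keV.tif", arr)
        if 2.1 in maps and 2.5 in maps:
            traces = rescale_trace_fractions(maps[2.1].fractions,
                                             maps[2.5].fractions["Mg"])
            for el, arr in traces.items():
                mcio.write_map_tiff(out / f"w_{el}_rescaled.tif", arr)

        # --- thickness binning + carbonate model --------------------------
        stage = "binning"
        bins = {}
        for e in (2.5, 4.2):
            if e in cubes:
                bins[e] = bin_by_thickness(cubes[e], thickness,
                                           config.bin_edges_um, matrix, det, geom)
                bins[e].to_csv(out / f"bins_{e:g}keV.csv", index=False)
        rim_mg_enhanced = None
        if 2.5 in bins and len(bins[2.5]) >= 3:
            b = bins[2.5].dropna(subset=["w_Mg"])
            slope = np.polyfit(b["t_mean_um"], b["w_Mg"], 1)[0]
            rim_mg_enhanced = bool(slope < 0)
            summary["mg_vs_thickness_slope_per_um"] = float(slope)
        carb = None
        if 4.2 in bins and len(bins[4.2]) >= 3:
            carb = carbonate_dilution_model(bins[4.2], matrix=matrix)
            summary["carbonate_dilution"] = {
                "slope_per_um": carb.slope, "intercept": carb.intercept,
                "r_squared": carb.r_squared,
            }

        # --- XANES line scan ----------------------------------------------
        stage = "xanes"
        r_mid = config.shape[0] // 2
        positions = [(r_mid, c) for c in range(config.shape[1])]
        specs, refs = render_xanes(scene, positions, noise_sigma=0.01)
        t_line = [scene.thickness_um[p] for p in positions]
        labels = [scene.regions[int(scene.region_label[p])].name
                  for p in positions]
        scan = line_scan_lcf(specs, [p[1] for p in positions], refs,
                             thickness_um=t_line, labels=labels,
                             thickness_threshold_um=config.mask_thresholds_um[1])
        scan.to_csv(out / "xanes_scan.csv", index=False)
        whit_rim_xanes = None
        core_share = scan.loc[scan.label == "core", "whit_share"]
        rim_share = scan.loc[scan.label.isin(["rim", "periphery"]), "whit_share"]
        if len(core_share) and len(rim_share):
            # require a clear margin so near-zero shares never flag
            whit_rim_xanes = bool(rim_share.mean() > core_share.mean() + 0.1)
            summary["whit_share"] = {"core": float(core_share.mean()),
                                     "rim": float(rim_share.mean())}

        # --- WAXS ---------------------------------------------------------
        stage = "waxs"
        profiles, q = render_waxs(scene)
        cls = classify_profiles(profiles, q, config.waxs_components)
        label_map = cls.labels.reshape(config.shape)
        mcio.write_map_tiff(out / "waxs_components.tif",
                            label_map.astype(float))
        whit_component = _whit_component(cls.components, q)
        whit_rim_waxs = False
        if whit_component is not None:
            in_whit = label_map == whit_component
            rim_like = (scene.region_label == RIM) | (scene.region_label == PERIPHERY)
            n_whit = int(in_whit.sum())
            confined = (float((in_whit & rim_like).sum()) / n_whit
                        if n_whit else 0.0)
            whit_rim_waxs = bool(n_whit > 0 and confined > 0.8)
            summary["waxs"] = {"whit_component": int(whit_component),
                               "whit_pixels": n_whit,
                               "whit_rim_confinement": confined}
        # refine the strongest mineral component
        strongest = cls.components[-1]
        phases = [scene.regions[CORE].phases[0][0]]
        ref = refine_profile(
            Profile1D(q, np.maximum(strongest, 0.0)), phases,
            background_anchors_q=[q[0], 10.5, 13.0, 28.0, q[-1]],
            q_range=(15.0, 34.0))
        summary["waxs_refined"] = {
            "phase": ref.phases[0].name,
            "a_angstrom": ref.phases[0].a, "c_angstrom": ref.phases[0].c,
            "domain_002_angstrom": ref.phases[0].domain_002,
            "domain_110_angstrom": ref.phases[0].domain_110,
        }

        # --- flags ---------------------------------------------------------
        stage = "summary"
        summary["flags"] = {
            "rim_Mg_enhanced": rim_mg_enhanced,
            "whit_rim_xanes": whit_rim_xanes,
            "whit_rim_waxs": whit_rim_waxs,
            "whit_rim": (bool(whit_rim_xanes and whit_rim_waxs)
                         if whit_rim_xanes is not None and whit_rim_waxs is not None
                         else None),
        }
        (out / "summary.json").write_text(
            json.dumps(_json_ready(summary), sort_keys=True, indent=2) + "\n")
        return summary
    except Exception as exc:
        (out / "summary.json").write_text(
            json.dumps(_json_ready({"error": str(exc), "stage": stage,
                                    **summary}), sort_keys=True, indent=2) + "\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _whit_component(components: np.ndarray, q: np.ndarray) -> int | None:
    """Index of the component that best matches the whitlockite pattern."""
    tmpl = synthesize_profile(q, WHIT_PHASE)
    tmpl = tmpl - tmpl.mean()
    best, best_corr = None, 0.35
    for i, comp in enumerate(components):
        c = comp - comp.mean()
        denom = np.linalg.norm(c) * np.linalg.norm(tmpl)
        if denom == 0:
            continue
        corr = float(c @ tmpl / denom)
        if corr > best_corr:
            best, best_corr = i, corr
    return best
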
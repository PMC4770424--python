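"""End-to-end orchestration: synthesize → process → outline → reconstruct → atlas.

Each stage is a plain function over in-memory objects; `run_pipeline` wires
them together, writes every product (response maps, outline JSON, surface
map GeoJSON/SVG, boundary table TSV/CSV) into a run directory, and logs
stage timings with a full parameter echo so any run is self-describing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .outline import PolarOutline, extract_outline
from .reconstruct import (
    InjectionSite,
    SurfaceMap,
    average_profiles,
    build_surface_map,
    downsample_profile,
    write_sites_csv,
)
from .response import ResponseMap, average_trials, compute_dff, lr_deconvolve, spatial_smooth
from .synthetic import (
    BANDS,
    CohortSpec,
    GroundTruthRegion,
    animal_jitter,
    default_truth,
    ground_truth_frame,
    render_trial_stack,
    simulate_injection_measurement,
    write_cohort,
)

logger = logging.getLogger("tonomap")

__all__ = [
    "PipelineError",
    "PipelineResult",
    "process_animal_stimulus",
    "band_outlines",
    "measure_sites",
    "analyze",
    "run_pipeline",
    "make_fixtures",
]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and propagate
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %-12s done in %.2f s", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("process")
def process_animal_stimulus(
    truth: Sequence[GroundTruthRegion],
    stimulus: str,
    cfg: PipelineConfig,
    animal_index: int,
) -> ResponseMap:
    """Trial-averaged, smoothed, deconvolved ΔF/F₀ map for one animal and
    stimulus."""
    spec = cfg.cohort
    proc = cfg.processing
    nb = spec.n_baseline_frames
    window = (nb, nb + min(proc.response_window_frames, spec.n_response_frames))
    maps = [
        compute_dff(render_trial_stack(truth, stimulus, spec, animal_index, t), window)
        for t in range(spec.n_trials)
    ]
    avg = average_trials(maps)
    steps = [
        lambda m: spatial_smooth(m, proc.smooth_size),
        lambda m: lr_deconvolve(m, proc.psf_width_um, proc.rl_iterations, proc.width_is_fwhm),
    ]
    if not proc.smooth_before_deconvolve:
        steps.reverse()
    for step in steps:
        avg = step(avg)
    avg.provenance["stimulus"] = stimulus
    avg.provenance["animal"] = animal_index
    return avg


def _clipped_window(
    row: int, col: int, half: int, shape: tuple[int, int]
) -> tuple[int, int, int, int]:
    h, w = shape
    return (max(0, row - half), min(h, row + half + 1), max(0, col - half), min(w, col + half + 1))


def locate_stimulus_peaks(
    rmap: ResponseMap,
    nominal_px: Mapping[tuple[str, str], tuple[float, float]],
    cfg: PipelineConfig,
) -> dict[tuple[str, str], tuple[int, int]]:
    """Match a stimulus map's response peaks to the nominal band centers.

    One stimulus can drive several bands at once (a 30-kHz tone activates
    the AAF, AI and AII high-frequency areas and the DM low area), and the
    whole constellation is shifted rigidly by the animal's positional
    jitter. Local maxima are therefore detected over the full map and
    paired with the nominal (published mean) centers by minimum total
    distance, which tolerates shifts far larger than the inter-focus
    spacing. Bands whose peak is not detected fall back to the brightest
    pixel within ``search_halfwidth_mm`` of their nominal center.
    """
    from scipy.optimize import linear_sum_assignment
    from skimage.feature import peak_local_max

    pitch = cfg.cohort.fov.pitch_mm
    keys = list(nominal_px)
    coords = peak_local_max(
        rmap.values,
        min_distance=max(1, int(round(0.2 / pitch))),
        threshold_rel=0.5,
        num_peaks=max(len(keys) * 2, 4),
    )
    out: dict[tuple[str, str], tuple[int, int]] = {}
    if len(coords):
        nom = np.array([nominal_px[k] for k in keys])
        cost = np.hypot(
            nom[:, 0:1] - coords[None, :, 0], nom[:, 1:2] - coords[None, :, 1]
        )
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            # Reject absurd matches (beyond the search window): fall back.
            if cost[i, j] <= 2 * cfg.processing.search_halfwidth_mm / pitch:
                out[keys[i]] = (int(coords[j][0]), int(coords[j][1]))
    half = int(round(cfg.processing.search_halfwidth_mm / pitch))
    for k in keys:
        if k not in out:
            r, c = nominal_px[k]
            r0, r1, c0, c1 = _clipped_window(int(round(r)), int(round(c)), half, rmap.values.shape)
            sub = rmap.values[r0:r1, c0:c1]
            pr, pc = np.unravel_index(int(np.argmax(sub)), sub.shape)
            out[k] = (r0 + pr, c0 + pc)
    return out


@_stage("outline")
def band_outlines(
    processed: Mapping[tuple[int, str], ResponseMap],
    cfg: PipelineConfig,
) -> tuple[dict[tuple[str, str], PolarOutline], dict[tuple[str, str], list]]:
    """Per-band averaged 72-sample outlines (mm) and per-animal extraction
    records.

    For each of the ten (region, band) areas, the corresponding stimulus
    map of every animal is trimmed around the band's nominal center, the
    0.05° outline extracted, profiles averaged by angle across animals,
    and the average downsampled to 5° bins.
    """
    from .synthetic import INJECTION_SITE_TABLE

    proc = cfg.processing
    fov = cfg.cohort.fov
    trim_half = int(round(proc.trim_halfwidth_mm / fov.pitch_mm))
    # One peak-matching pass per (animal, stimulus) map, shared by its bands.
    peak_px: dict[tuple[int, str], dict[tuple[str, str], tuple[int, int]]] = {}
    for (a, stim) in processed:
        nominal = {
            (r, b): fov.mm_to_px(*INJECTION_SITE_TABLE[(r, b)][0:3:2])
            for r, b, s in BANDS
            if s == stim
        }
        peak_px[(a, stim)] = locate_stimulus_peaks(processed[(a, stim)], nominal, cfg)
    averaged: dict[tuple[str, str], PolarOutline] = {}
    per_animal: dict[tuple[str, str], list] = {}
    for region, band, stimulus in BANDS:
        profiles = []
        records = []
        for a in range(cfg.cohort.n_animals):
            rmap = processed[(a, stimulus)]
            peak = peak_px[(a, stimulus)][(region, band)]
            prof = extract_outline(
                rmap,
                bbox=_clipped_window(*peak, trim_half, rmap.values.shape),
                frac=proc.threshold_frac,
                upsample_factor=proc.upsample_factor,
                d_theta_deg=proc.d_theta_deg,
                connectivity=proc.connectivity,
            )
            profiles.append(prof.to_mm())
            rc, dv = cfg.cohort.fov.px_to_mm(*prof.center)
            records.append({"animal": a, "center_rc_mm": rc, "center_dv_mm": dv, "profile": prof})
        averaged[(region, band)] = downsample_profile(
            average_profiles(profiles), proc.downsample_factor
        )
        per_animal[(region, band)] = records
    return averaged, per_animal


@_stage("sites")
def measure_sites(
    truth: Sequence[GroundTruthRegion],
    cfg: PipelineConfig,
) -> list[InjectionSite]:
    """Simulated stereotaxic injection-site table (mean ± SEM per band).

    Each animal contributes one measurement per band: the true focus
    center displaced by that animal's jitter, read out with Gaussian
    measurement noise and atlas-plate snapping; per-band means and SEMs
    over animals form the site table.
    """
    spec = cfg.cohort
    inj = cfg.injection
    focus_by_band = {
        (r.label, band): f
        for r in truth
        for f in r.foci
        for reg, band, stim in BANDS
        if reg == r.label and stim == f.stimulus
    }
    rng = np.random.default_rng([spec.seed, 983])
    sites = []
    for region, band, _stim in BANDS:
        f = focus_by_band[(region, band)]
        draws = []
        for a in range(spec.n_animals):
            drc, ddv = animal_jitter(spec, a)
            m = simulate_injection_measurement(
                (f.rc_mm + drc, f.dv_mm + ddv),
                inj.measurement_sd_mm,
                rng,
                snap=inj.snap,
                snap_step_mm=inj.snap_step_mm,
            )
            draws.append((m.rc_mm, m.dv_mm))
        arr = np.array(draws)
        mean = arr.mean(axis=0)
        n = len(draws)
        sem = arr.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(2)
        # Small simulated cohorts can put a band mean marginally outside
        # the 2.0–4.0 gridline window; the map itself tolerates that.
        sites.append(
            InjectionSite(
                region, band, float(mean[0]), float(mean[1]), n,
                float(sem[0]), float(sem[1]), check_range=False,
            )
        )
    return sites


@dataclass
class PipelineResult:
    """Everything one end-to-end analysis produced, in memory."""

    truth: list[GroundTruthRegion]
    processed: dict[tuple[int, str], ResponseMap]
    averaged_outlines: dict[tuple[str, str], PolarOutline]
    outline_records: dict[tuple[str, str], list]
    sites: list[InjectionSite]
    surface_map: SurfaceMap
    boundary_table: object

    def recovered_centers(self) -> dict[tuple[str, str], tuple[float, float]]:
        """Per-band mean imaging-derived outline center (rc_mm, dv_mm)."""
        out = {}
        for key, records in self.outline_records.items():
            rc = float(np.mean([r["center_rc_mm"] for r in records]))
            dv = float(np.mean([r["center_dv_mm"] for r in records]))
            out[key] = (rc, dv)
        return out


def analyze(cfg: PipelineConfig) -> PipelineResult:
    """Run the full analysis in memory: synthesize, process every animal ×
    stimulus, outline the ten bands, measure the site table, reconstruct
    the surface map and project the boundary table."""
    truth = default_truth(cfg.truth_radius_mm, cfg.truth_amplitude)
    stimuli = sorted({s for _r, _b, s in BANDS})
    processed: dict[tuple[int, str], ResponseMap] = {}
    for a in range(cfg.cohort.n_animals):
        for stim in stimuli:
            processed[(a, stim)] = process_animal_stimulus(truth, stim, cfg, a)
    averaged, records = band_outlines(processed, cfg)
    sites = measure_sites(truth, cfg)
    smap = _reconstruct(sites, averaged, cfg)
    table = _atlas(smap, cfg)
    return PipelineResult(truth, processed, averaged, records, sites, smap, table)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full analysis into ``out_dir`` and return it.

    Deterministic given the cohort seed: outline JSON, site CSV, GeoJSON
    and boundary tables are byte-identical across reruns of the same
    config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        cfg.to_yaml(out / "config.yaml")
        logger.info("parameters: %s", json.dumps(cfg.model_dump(mode="json")))

        res = analyze(cfg)
        ground_truth_frame(res.truth).to_csv(out / "ground_truth.csv", index=False)
        if cfg.save_stacks:
            write_cohort(res.truth, cfg.cohort, out / "stacks")

        maps_dir = out / "response_maps"
        maps_dir.mkdir(exist_ok=True)
        for (a, stim), rmap in res.processed.items():
            _write_response_map(rmap, maps_dir / f"animal{a:02d}_{stim}")

        outlines_dir = out / "outlines"
        outlines_dir.mkdir(exist_ok=True)
        for (region, band), prof in res.averaged_outlines.items():
            prof.to_json(outlines_dir / f"{region}_{band}.json")

        centers = res.recovered_centers()
        pd.DataFrame(
            [
                {"region": r, "band": b, "rc_mm": c[0], "dv_mm": c[1]}
                for (r, b), c in centers.items()
            ]
        ).to_csv(out / "imaging_centers.csv", index=False)

        write_sites_csv(res.sites, out / "injection_sites.csv")
        res.surface_map.to_geojson(out / "surface_map.geojson")
        res.surface_map.to_svg(out / "surface_map.svg")
        res.boundary_table.to_tsv(out / "boundary_table.tsv")
        res.boundary_table.to_tidy_csv(out / "boundary_table.csv")
        if cfg.atlas.render_overlays:
            from .atlas import render_coronal_overlays

            render_coronal_overlays(res.boundary_table, out_dir=out / "coronal")
        logger.info("run complete: %s", out)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()


@_stage("reconstruct")
def _reconstruct(sites, averaged, cfg: PipelineConfig) -> SurfaceMap:
    return build_surface_map(
        sites, averaged, cfg.processing.k_intermediates, cfg.processing.resample_deg
    )


@_stage("atlas")
def _atlas(smap: SurfaceMap, cfg: PipelineConfig):
    from .atlas import gridline_boundaries

    return gridline_boundaries(
        smap,
        cfg.atlas.rc_start_mm,
        cfg.atlas.rc_end_mm,
        cfg.atlas.step_mm,
        cfg.atlas.decimals,
    )


def _write_response_map(rmap: ResponseMap, stem: Path) -> None:
    import tifffile

    tifffile.imwrite(stem.with_suffix(".tif"), rmap.values.astype(np.float32))
    stem.with_suffix(".json").write_text(
        json.dumps(
            {"pixel_pitch_um": rmap.pixel_pitch_um, "provenance": rmap.provenance},
            indent=1,
            default=str,
        )
    )


def make_fixtures(seed: int, out_dir: str | Path) -> Path:
    """Generate a small, fast cohort for tests and demos.

    Half-resolution frames (64×84 px at 40.8 μm/px cover the same field of
    view), 2 animals, 3 trials; regenerating with the same seed reproduces
    the files bit-for-bit. Returns the manifest path.
    """
    spec = CohortSpec(
        n_animals=2,
        n_trials=3,
        pixel_pitch_um=40.8,
        image_shape=(64, 84),
        seed=seed,
    )
    return write_cohort(default_truth(), spec, out_dir)
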
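"""Ground-truthed synthetic imaging cohorts for the auditory-cortex mapper.

Emulates the study conditions of the widefield flavoprotein experiment:
128×168-pixel frames at 20.4 μm/px and 9.7 Hz, 20 trials per stimulus,
~300-μm tonal response foci at the stereotaxic positions of the six
auditory regions (AAF, AI, AII, DA, DM, DP), with per-animal positional
jitter and per-pixel sensor noise. Every downstream stage of the pipeline
can therefore be tested against known truth without any animal data.

Coordinate conventions
----------------------
Stereotaxic surface coordinates are (rc_mm, dv_mm): rostrocaudal distance
from bregma (increasing caudally) and dorsoventral distance from the dorsal
edge of the rhinal fissure (increasing dorsally). In image space, columns
increase with RC and rows increase ventrally (row 0 is dorsal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .reconstruct import InjectionSite
from .response import TrialStack

__all__ = [
    "REGIONS",
    "TONOTOPIC_REGIONS",
    "BANDS",
    "INJECTION_SITE_TABLE",
    "Focus",
    "GroundTruthRegion",
    "CohortSpec",
    "FieldOfView",
    "default_truth",
    "default_sites",
    "animal_jitter",
    "render_trial_stack",
    "render_response_frame",
    "simulate_injection_measurement",
    "write_cohort",
    "ground_truth_frame",
]

REGIONS = ("AAF", "AI", "AII", "DA", "DM", "DP")
TONOTOPIC_REGIONS = ("AAF", "AI", "AII", "DM")

#: The ten (region, band) response areas and the stimulus that drives each.
#: Tonotopic regions have a low- and a high-frequency focus (5→30 kHz, or
#: 30→60 kHz in DM); DA and DP respond to the FM direction-reversal stimulus.
BANDS: tuple[tuple[str, str, str], ...] = (
    ("AAF", "low", "5kHz"),
    ("AAF", "high", "30kHz"),
    ("AI", "low", "5kHz"),
    ("AI", "high", "30kHz"),
    ("AII", "low", "5kHz"),
    ("AII", "high", "30kHz"),
    ("DA", "fm", "FM"),
    ("DM", "low", "30kHz"),
    ("DM", "high", "60kHz"),
    ("DP", "fm", "FM"),
)

#: Published mean injection-site coordinates per (region, band):
#: (rc_mm, sem_rc, dv_mm, sem_dv, n).  RC is measured from bregma
#: (posterior positive), DV from the dorsal tip of the rhinal fissure.
INJECTION_SITE_TABLE: dict[tuple[str, str], tuple[float, float, float, float, int]] = {
    ("AAF", "low"): (2.38, 0.05, 1.16, 0.08, 5),
    ("AAF", "high"): (2.72, 0.08, 0.67, 0.05, 4),
    ("AI", "low"): (3.58, 0.03, 1.29, 0.14, 5),
    ("AI", "high"): (3.17, 0.06, 1.06, 0.05, 5),
    ("AII", "low"): (3.12, 0.02, 0.71, 0.13, 4),
    ("AII", "high"): (3.13, 0.02, 0.32, 0.10, 5),
    ("DA", "fm"): (2.70, 0.09, 1.46, 0.13, 6),
    ("DM", "low"): (3.13, 0.14, 1.58, 0.03, 3),
    ("DM", "high"): (2.89, 0.03, 1.92, 0.17, 4),
    ("DP", "fm"): (3.37, 0.12, 1.95, 0.12, 5),
}

STIMULI = ("5kHz", "30kHz", "60kHz", "FM")

#: Raised-cosine focus profiles put their 60%-of-peak level exactly at the
#: base contour: G(r) = (1 + cos(π·r/(s·R)))/2 with s = π/arccos(0.2), so
#: G(R) = 0.6 and G reaches 0 at s·R ≈ 2.29·R, outside the contour. The
#: base contour is therefore directly the ground-truth responsive-area
#: outline that the >60% threshold recovers.
SHOULDER_SCALE = float(np.pi / np.arccos(0.2))


def _circle(radius_mm: float) -> Callable[[np.ndarray], np.ndarray]:
    def shape(theta_deg: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(theta_deg, dtype=float), radius_mm)

    return shape


@dataclass
class Focus:
    """One tonal/FM response focus: stimulus tag, stereotaxic center and
    base contour radius as a function of angle (mm)."""

    stimulus: str
    rc_mm: float
    dv_mm: float
    area_shape: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self) -> None:
        if not (2.0 <= self.rc_mm <= 4.0):
            raise ValueError(f"rc_mm {self.rc_mm} outside the atlas range [2.0, 4.0]")
        if self.dv_mm < 0:
            raise ValueError("dv_mm must be >= 0")
        probe = self.area_shape(np.arange(0.0, 360.0, 5.0))
        if not np.all(probe > 0):
            raise ValueError("area_shape must be strictly positive at every angle")


_EXPECTED_TAGS = {
    "AAF": {"5kHz", "30kHz"},
    "AI": {"5kHz", "30kHz"},
    "AII": {"5kHz", "30kHz"},
    "DM": {"30kHz", "60kHz"},
    "DA": {"FM"},
    "DP": {"FM"},
}


@dataclass
class GroundTruthRegion:
    """Ground truth for one cortical region: its response foci and peak
    ΔF/F₀ amplitude (dimensionless; flavoprotein responses are typically
    1–3%)."""

    label: str
    foci: list[Focus]
    response_amplitude: float = 0.02

    def __post_init__(self) -> None:
        if self.label not in REGIONS:
            raise ValueError(f"unknown region {self.label!r}")
        tags = {f.stimulus for f in self.foci}
        if tags != _EXPECTED_TAGS[self.label]:
            raise ValueError(
                f"{self.label} must have foci tagged {_EXPECTED_TAGS[self.label]}, got {tags}"
            )


class FieldOfView(BaseModel):
    """Affine mapping between stereotaxic mm and image pixels.

    Defaults place the ten response foci (RC 2.38–3.58 mm, DV 0.32–1.95 mm)
    comfortably inside a 128×168 frame at 20.4 μm/px, with enough margin to
    trim a window around every focus.
    """

    rc_at_col0_mm: float = 1.50
    dv_at_row0_mm: float = 2.55
    pixel_pitch_um: float = 20.4

    @property
    def pitch_mm(self) -> float:
        return self.pixel_pitch_um / 1000.0

    def mm_to_px(self, rc_mm: float, dv_mm: float) -> tuple[float, float]:
        """(rc, dv) in mm → fractional (row, col)."""
        col = (rc_mm - self.rc_at_col0_mm) / self.pitch_mm
        row = (self.dv_at_row0_mm - dv_mm) / self.pitch_mm
        return row, col

    def px_to_mm(self, row: float, col: float) -> tuple[float, float]:
        rc = self.rc_at_col0_mm + col * self.pitch_mm
        dv = self.dv_at_row0_mm - row * self.pitch_mm
        return rc, dv


class CohortSpec(BaseModel):
    """Study conditions for one synthetic cohort.

    Defaults are the acquisition parameters of the emulated experiment
    (20 trials, 5 baseline frames, 9.7 Hz, 20.4 μm/px, 128×168 after
    binning) plus a positional jitter of 0.1 mm SD per animal and pixel
    noise at 20% of the response amplitude.
    """

    n_animals: int = Field(5, ge=1)
    jitter_sd_mm: float = Field(0.1, ge=0)
    per_focus_jitter_sd_mm: float = Field(0.0, ge=0)
    noise_sd: float = Field(0.004, ge=0)  # ΔF/F₀ units per pixel per frame
    n_trials: int = Field(20, ge=1)
    n_baseline_frames: int = Field(5, ge=1)
    n_response_frames: int = Field(5, ge=1)
    frame_rate_hz: float = Field(9.7, gt=0)
    pixel_pitch_um: float = Field(20.4, gt=0)
    image_shape: tuple[int, int] = (128, 168)
    baseline_counts: float = Field(1000.0, gt=0)
    seed: int = 0
    fov: FieldOfView | None = None

    @model_validator(mode="after")
    def _sync_fov(self) -> "CohortSpec":
        if self.fov is None:
            self.fov = FieldOfView(pixel_pitch_um=self.pixel_pitch_um)
        elif self.fov.pixel_pitch_um != self.pixel_pitch_um:
            raise ValueError("fov pixel pitch must match the cohort pixel pitch")
        return self


def default_truth(radius_mm: float = 0.15, amplitude: float = 0.02) -> list[GroundTruthRegion]:
    """Ground truth with the ten focus centers at the published mean
    injection-site coordinates and near-circular base contours."""
    foci: dict[str, list[Focus]] = {label: [] for label in REGIONS}
    for region, band, stim in BANDS:
        rc, _sr, dv, _sd, _n = INJECTION_SITE_TABLE[(region, band)]
        foci[region].append(Focus(stim, rc, dv, _circle(radius_mm)))
    return [GroundTruthRegion(label, foci[label], amplitude) for label in REGIONS]


def default_sites() -> list[InjectionSite]:
    """The published mean injection sites as `InjectionSite` records."""
    return [
        InjectionSite(region, band, rc, dv, n, sr, sd)
        for (region, band), (rc, sr, dv, sd, n) in INJECTION_SITE_TABLE.items()
    ]


def ground_truth_frame(truth: Sequence[GroundTruthRegion]) -> pd.DataFrame:
    """Tabulate the true focus centers (columns region, stimulus, rc_mm, dv_mm)."""
    rows = [
        {"region": r.label, "stimulus": f.stimulus, "rc_mm": f.rc_mm, "dv_mm": f.dv_mm}
        for r in truth
        for f in r.foci
    ]
    return pd.DataFrame(rows)


def animal_jitter(spec: CohortSpec, animal_index: int) -> tuple[float, float]:
    """Rigid (Δrc, Δdv) translation for one animal, in mm.

    All foci of an animal move together (the brain sits at a slightly
    different place under the window), a deterministic function of
    (seed, animal_index).
    """
    rng = np.random.default_rng([spec.seed, animal_index])
    drc, ddv = rng.normal(size=2) * spec.jitter_sd_mm
    return float(drc), float(ddv)


def _focus_offsets(spec: CohortSpec, animal_index: int, n_foci: int) -> np.ndarray:
    """Optional independent per-focus jitter, drawn after the rigid term
    from the same per-animal stream (deterministic in seed, animal)."""
    rng = np.random.default_rng([spec.seed, animal_index])
    rng.normal(size=2)  # consume the rigid draw to keep streams aligned
    if spec.per_focus_jitter_sd_mm > 0:
        return rng.normal(0.0, spec.per_focus_jitter_sd_mm, size=(n_foci, 2))
    return np.zeros((n_foci, 2))


def render_response_frame(
    truth: Sequence[GroundTruthRegion],
    stimulus: str,
    spec: CohortSpec,
    animal_index: int,
) -> np.ndarray:
    """Noise-free fractional response image A·G(x) for one stimulus.

    G is a raised-cosine profile: 1 at the focus center, 0.6 at the base
    contour radius R(θ), falling smoothly to 0 at ~2.29·R(θ); every focus
    tagged with ``stimulus`` (across regions) contributes, displaced by
    the animal's jitter.
    """
    if stimulus not in {f.stimulus for r in truth for f in r.foci}:
        raise ValueError(f"stimulus {stimulus!r} not present in the ground truth")
    if animal_index >= spec.n_animals:
        raise ValueError("animal_index out of range for this cohort")
    h, w = spec.image_shape
    fov = spec.fov
    drc, ddv = animal_jitter(spec, animal_index)
    all_foci = [(r, f) for r in truth for f in r.foci]
    offsets = _focus_offsets(spec, animal_index, len(all_foci))
    img = np.zeros((h, w), dtype=float)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for (region, focus), (frc, fdv) in zip(all_foci, offsets):
        if focus.stimulus != stimulus:
            continue
        rc = focus.rc_mm + drc + frc
        dv = focus.dv_mm + ddv + fdv
        crow, ccol = fov.mm_to_px(rc, dv)
        dx_mm = (cols - ccol) * fov.pitch_mm  # +RC
        dy_mm = (crow - rows) * fov.pitch_mm  # +DV
        r_mm = np.hypot(dx_mm, dy_mm)
        theta = np.degrees(np.arctan2(dy_mm, dx_mm)) % 360.0
        r_zero = SHOULDER_SCALE * focus.area_shape(theta)
        frac = np.clip(r_mm / r_zero, 0.0, 1.0)
        g = 0.5 * (1.0 + np.cos(np.pi * frac))
        g[r_mm >= r_zero] = 0.0
        img += region.response_amplitude * g
    return img


def render_trial_stack(
    truth: Sequence[GroundTruthRegion],
    stimulus: str,
    spec: CohortSpec,
    animal_index: int,
    trial_index: int = 0,
) -> TrialStack:
    """Render one trial's raw frame stack for one animal and stimulus.

    Frames hold the constant baseline F_b for ``n_baseline_frames``, then
    F_b·(1 + A·G(x)) for ``n_response_frames``; i.i.d. Gaussian noise of
    ``noise_sd``·F_b is added per pixel per frame. The jitter draw depends
    only on (seed, animal_index); the noise stream additionally on the
    stimulus and trial, so repeated calls are bit-identical.
    """
    if spec.baseline_counts <= 0:
        raise ValueError("baseline_counts must be positive")
    signal = render_response_frame(truth, stimulus, spec, animal_index)
    fb = spec.baseline_counts
    nb, nr = spec.n_baseline_frames, spec.n_response_frames
    frames = np.empty((nb + nr, *spec.image_shape), dtype=float)
    frames[:nb] = fb
    frames[nb:] = fb * (1.0 + signal)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(
            [spec.seed, animal_index, STIMULI.index(stimulus), trial_index]
        )
        frames = frames + rng.normal(0.0, spec.noise_sd * fb, size=frames.shape)
        np.clip(frames, 1e-6, None, out=frames)
    return TrialStack(frames, spec.pixel_pitch_um, spec.frame_rate_hz, nb)


def simulate_injection_measurement(
    true_center: tuple[float, float],
    measurement_sd_mm: float,
    seed: int | np.random.Generator,
    region: str = "",
    band: str = "",
    snap: bool = True,
    snap_step_mm: float = 0.02,
) -> InjectionSite:
    """One simulated stereotaxic measurement of an injection site.

    Stands in for the tracer-histology readout: independent Gaussian
    measurement noise on both axes, with the RC coordinate optionally
    snapped to the nearest ``snap_step_mm`` (atlas plates discretize the
    rostrocaudal judgement).
    """
    if measurement_sd_mm < 0:
        raise ValueError("measurement_sd_mm must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rc, dv = true_center
    if measurement_sd_mm > 0:
        rc += rng.normal(0.0, measurement_sd_mm)
        dv += rng.normal(0.0, measurement_sd_mm)
    if snap:
        rc = round(rc / snap_step_mm) * snap_step_mm
    return InjectionSite(
        region=region, band=band, rc_mm=rc, dv_mm=dv, n=1, check_range=False
    )


def write_cohort(
    truth: Sequence[GroundTruthRegion],
    spec: CohortSpec,
    out_dir: str | Path,
    stimuli: Sequence[str] | None = None,
) -> Path:
    """Write a cohort to disk: one multi-page TIFF per animal × stimulus
    (4-D: trial × frame × rows × cols), a JSON manifest, and the ground
    truth as CSV. Returns the manifest path."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if stimuli is None:
        stimuli = sorted({f.stimulus for r in truth for f in r.foci}, key=STIMULI.index)
    files = []
    for a in range(spec.n_animals):
        for stim in stimuli:
            stack = np.stack(
                [
                    render_trial_stack(truth, stim, spec, a, t).frames
                    for t in range(spec.n_trials)
                ]
            )
            name = f"animal{a:02d}_{stim}.tif"
            tifffile.imwrite(out_dir / name, stack.astype(np.float32))
            files.append({"animal": a, "stimulus": stim, "file": name})
    manifest = {
        "pixel_pitch_um": spec.pixel_pitch_um,
        "frame_rate_hz": spec.frame_rate_hz,
        "n_trials": spec.n_trials,
        "n_baseline_frames": spec.n_baseline_frames,
        "n_response_frames": spec.n_response_frames,
        "image_shape": list(spec.image_shape),
        "seed": spec.seed,
        "stimuli": list(stimuli),
        "fov": spec.fov.model_dump(),
        "axis_convention": "col=+RC (caudal), row=-DV (row 0 dorsal)",
        "files": files,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    ground_truth_frame(truth).to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest_path
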
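"""Synthetic microscopy, tracking, qPCR and flow-cytometry data generators.

Every input the quantification stack consumes can be produced here under a
documented generative model, together with a ground-truth table keyed by
stable identifiers.  The generators emulate the study conditions of a
live-cell repeat-methylation reporter experiment:

* fixed-cell stacks: 7 confocal slices, a DNA-stain channel plus a reporter
  channel in which each nucleus carries 2–3 bright diffraction-limited spots;
* live-cell movies: diffusive spot motion sampled at 0.1 s per frame;
* MSRE-qPCR plates: a methylation-sensitive amplicon whose Ct is delayed by
  digestion of the unmethylated template fraction, next to an undigested
  control amplicon used for input normalization, plus RT-qPCR rows with a
  reference gene;
* flow cytometry: log-normal reporter-positive populations over an
  autofluorescence-like negative component, with a paired parental control.

Condition presets encode the direction and size of the biological effects the
pipeline is meant to recover: drug-induced DNA-hypomethylation halves the
methylated fraction, dense cultures are hypomethylated relative to sparse
ones and show dimmer reporter spots and slower spot motion, and TET
inhibition raises nuclear 5mC-stain intensity 1.5-fold.  Preset magnitudes
are constants in :data:`SCENE_PRESETS` / :data:`QPCR_PRESETS`, not
hard-coded in the generators.

All generators are deterministic functions of their ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stacks import ImageStack

__all__ = [
    "SceneConfig",
    "MotionConfig",
    "QPCRSimConfig",
    "FlowSimConfig",
    "GroundTruth",
    "ScenePreset",
    "SCENE_PRESETS",
    "QPCR_PRESETS",
    "PlacementError",
    "simulate_nuclei_stack",
    "simulate_trajectories",
    "render_movie",
    "simulate_qpcr_plate",
    "qpcr_preset",
    "simulate_flow_population",
    "build_msre_amplicon",
]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap (overcrowded scene)."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and photometry of a synthetic fixed-cell field of view.

    Intensity units are arbitrary; the µm scale enters only through
    ``pixel_size``.  ``spot_amplitude`` is the peak height of a reporter spot
    above the nuclear background; ``nuclear_background`` /
    ``extranuclear_background`` are the reporter-channel plateau levels inside
    and outside nuclei; ``dna_intensity`` is the DNA-stain plateau inside
    nuclei.  Gaussian read noise of sd ``noise_sd`` is added to every pixel of
    every slice.
    """

    image_width: int = 256
    image_height: int = 256
    n_slices: int = 7
    n_nuclei: int = 10
    nucleus_radius_range: tuple[float, float] = (15.0, 25.0)
    spots_per_nucleus_range: tuple[int, int] = (2, 3)
    spot_sigma: float = 2.0
    spot_amplitude: float = 300.0
    dna_intensity: float = 200.0
    nuclear_background: float = 40.0
    extranuclear_background: float = 10.0
    noise_sd: float = 5.0
    pixel_size: float = 0.1  # µm per pixel
    border_margin: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_width < 8 or self.image_height < 8:
            raise ValueError("image dimensions must be at least 8 px")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ValueError("nucleus_radius_range must satisfy 0 < lo <= hi")
        slo, shi = self.spots_per_nucleus_range
        if not (0 <= slo <= shi):
            raise ValueError("spots_per_nucleus_range must satisfy 0 <= lo <= hi")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be > 0")
        for name in ("spot_amplitude", "dna_intensity", "nuclear_background",
                     "extranuclear_background", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass(frozen=True)
class MotionConfig:
    """Parameters of the spot-motion truth model.

    ``diffusion_coefficient`` D is in µm²/s; per-axis Brownian increments have
    variance ``2 D Δt``.  Observed coordinates add i.i.d. Gaussian
    localization noise of sd ``localization_sd`` (µm).  The confined model
    reflects the radial excursion from the start position at
    ``confinement_radius``.
    """

    n_trajectories: int = 50
    n_frames: int = 100
    frame_interval: float = 0.1  # s
    diffusion_coefficient: float = 0.01  # µm²/s
    localization_sd: float = 0.02  # µm
    motion_model: str = "brownian"
    confinement_radius: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2 (no displacement otherwise)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if self.localization_sd < 0:
            raise ValueError("localization_sd must be >= 0")
        if self.motion_model not in ("brownian", "confined"):
            raise ValueError("motion_model must be 'brownian' or 'confined'")
        if self.motion_model == "confined" and not (
            self.confinement_radius and self.confinement_radius > 0
        ):
            raise ValueError("confined model requires confinement_radius > 0")


#: Ct value used for reactions whose template is fully destroyed.
UNDETERMINED_CT = float("nan")


@dataclass(frozen=True)
class QPCRSimConfig:
    """Generative model of an MSRE-/RT-qPCR plate.

    Each condition is a ``(name, true_methylated_fraction, true_expression_fold)``
    triple.  The digestion model is all-or-nothing at the amplicon level: a
    fraction ``f`` of MSRE-amplicon templates is methylation-protected and
    survives digestion, so its Ct is delayed by ``log_E(1/f)`` cycles relative
    to the undigested control amplicon.  Setting ``per_site_count`` = k
    switches to a per-site model where ``f`` is the per-site methylation
    probability and the amplifiable fraction is ``f**k``.  A per-sample
    input-amount shift (sd ``biological_sd`` cycles) is shared by both
    amplicons and cancels in ΔCt.
    """

    conditions: tuple[tuple[str, float, float], ...] = (
        ("mock", 0.8, 1.0),
        ("treated", 0.4, 2.0),
    )
    ct_baseline: float = 24.0
    efficiency: float = 2.0
    technical_sd: float = 0.2
    biological_sd: float = 0.5
    n_technical: int = 3
    n_biological: int = 3
    include_expression: bool = True
    expr_reference_baseline: float = 18.0
    expr_target_offset: float = 6.0
    per_site_count: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.conditions:
            raise ValueError("at least one condition required")
        for name, frac, fold in self.conditions:
            if not 0 <= frac <= 1:
                raise ValueError(f"methylated fraction for {name!r} must be in [0, 1]")
            if fold < 0:
                raise ValueError(f"expression fold for {name!r} must be >= 0")
        if not (1 < self.efficiency <= 2):
            raise ValueError("efficiency must be in (1, 2]")
        if self.technical_sd < 0 or self.biological_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if self.n_technical < 1 or self.n_biological < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.per_site_count is not None and self.per_site_count < 1:
            raise ValueError("per_site_count must be >= 1 when given")


@dataclass(frozen=True)
class FlowSimConfig:
    """Log-normal reporter population over an autofluorescence component."""

    n_events: int = 10_000
    log_mean: float = 7.0  # natural-log intensity of the positive population
    log_sd: float = 0.5
    negative_fraction: float = 0.1
    negative_log_mean: float = 4.0
    negative_log_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be > 0")
        if not 0 <= self.negative_fraction <= 1:
            raise ValueError("negative_fraction must be in [0, 1]")
        if self.log_sd < 0 or self.negative_log_sd < 0:
            raise ValueError("log sds must be >= 0")


@dataclass
class GroundTruth:
    """Per-object truth tables, one row per generated object."""

    nuclei: pd.DataFrame = field(default_factory=pd.DataFrame)
    spots: pd.DataFrame = field(default_factory=pd.DataFrame)
    trajectories: pd.DataFrame = field(default_factory=pd.DataFrame)
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# condition presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenePreset:
    """Multiplicative scene modifiers for one biological condition.

    ``amplitude_scale`` scales reporter-spot amplitude (methylation-sensor
    signal); ``nuclear_scale`` scales the whole within-nucleus reporter
    intensity (spots and plateau), the knob used for 5mC-stain readouts.
    """

    amplitude_scale: float = 1.0
    nuclear_scale: float = 1.0


#: Documented condition presets for :func:`simulate_nuclei_stack`.  Dense
#: cultures and demethylating-drug treatment halve the sensor-spot amplitude;
#: TET inhibition (bobcat) raises total nuclear 5mC-stain intensity 1.5-fold.
SCENE_PRESETS: dict[str, ScenePreset] = {
    "none": ScenePreset(),
    "mock": ScenePreset(),
    "sparse": ScenePreset(),
    "dense": ScenePreset(amplitude_scale=0.5),
    "aza_treated": ScenePreset(amplitude_scale=0.5),
    "bobcat_treated": ScenePreset(nuclear_scale=1.5),
}


#: Documented condition presets for :func:`simulate_qpcr_plate`:
#: (condition name, true methylated fraction, true expression fold).
#: Drug treatment halves the methylated fraction relative to mock in both
#: cell-line presets; dense cultures sit below sparse ones and transcribe
#: the repeats more.
QPCR_PRESETS: dict[str, tuple[tuple[str, float, float], ...]] = {
    "mcf10a_aza": (("mock", 0.8, 1.0), ("aza_treated", 0.4, 2.0)),
    "mcf7_aza": (("mock", 0.7, 1.0), ("aza_treated", 0.35, 2.0)),
    "mcf10a_density": (("sparse", 0.8, 1.0), ("dense", 0.55, 2.0)),
}


def qpcr_preset(name: str, seed: int = 0, **overrides) -> QPCRSimConfig:
    """Build a :class:`QPCRSimConfig` from a named preset."""
    try:
        conditions = QPCR_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown qPCR preset {name!r}; known: {sorted(QPCR_PRESETS)}") from None
    return replace(QPCRSimConfig(conditions=conditions, seed=seed), **overrides)


# ---------------------------------------------------------------------------
# fixed-cell scenes
# ---------------------------------------------------------------------------


def _place_nuclei(cfg: SceneConfig, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping nuclei fully inside the field."""
    placed: list[tuple[float, float, float]] = []
    lo, hi = cfg.nucleus_radius_range
    for i in range(cfg.n_nuclei):
        for _attempt in range(500):
            r = rng.uniform(lo, hi)
            ylim = (cfg.border_margin + r, cfg.image_height - cfg.border_margin - r)
            xlim = (cfg.border_margin + r, cfg.image_width - cfg.border_margin - r)
            if ylim[0] >= ylim[1] or xlim[0] >= xlim[1]:
                raise PlacementError(
                    f"nucleus radius up to {hi} px cannot fit in a "
                    f"{cfg.image_height}x{cfg.image_width} px field with "
                    f"border_margin={cfg.border_margin}"
                )
            cy = rng.uniform(*ylim)
            cx = rng.uniform(*xlim)
            if all(math.hypot(cy - py, cx - px) > r + pr + 2 for py, px, pr in placed):
                placed.append((cy, cx, r))
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{cfg.n_nuclei} after 500 attempts; "
                f"n_nuclei={cfg.n_nuclei} with radii in {cfg.nucleus_radius_range} "
                f"overcrowds a {cfg.image_height}x{cfg.image_width} px field"
            )
    return placed


def _add_gaussian_spot(img: np.ndarray, y: float, x: float, amplitude: float, sigma: float) -> None:
    """Add a 2-D Gaussian of peak ``amplitude`` in place (local window, ±4σ)."""
    h, w = img.shape
    half = int(math.ceil(4 * sigma))
    y0, y1 = max(0, int(y) - half), min(h, int(y) + half + 1)
    x0, x1 = max(0, int(x) - half), min(w, int(x) + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2)
    )


def simulate_nuclei_stack(
    cfg: SceneConfig, condition_preset: str = "none"
) -> tuple[ImageStack, GroundTruth]:
    """Render a 2-channel (DNA stain, reporter) confocal stack plus its truth.

    Nuclei are discs with Gaussian-smoothed edges placed without overlap;
    each carries a sampled number of reporter spots, rendered as lateral
    Gaussians with a Gaussian axial profile peaking at a random central
    slice so that a maximum projection recovers the full amplitude.

    Returns
    -------
    (stack, truth)
        ``stack.channel_names == ("dna", "reporter")``; ``truth.nuclei`` and
        ``truth.spots`` list every generated object.
    """
    cfg.validate()
    try:
        preset = SCENE_PRESETS[condition_preset]
    except KeyError:
        raise KeyError(
            f"unknown scene preset {condition_preset!r}; known: {sorted(SCENE_PRESETS)}"
        ) from None

    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_height, cfg.image_width
    nuclei = _place_nuclei(cfg, rng)

    # within-nucleus weight in [0, 1] with a smoothed (Gaussian) edge
    profile = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for cy, cx, r in nuclei:
        profile[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 1.0
    if nuclei:
        profile = gaussian_filter(profile, sigma=1.0)

    amp = cfg.spot_amplitude * preset.amplitude_scale * preset.nuclear_scale
    nuclear_bg = cfg.nuclear_background * preset.nuclear_scale

    dna_base = cfg.extranuclear_background + profile * (cfg.dna_intensity - cfg.extranuclear_background)
    reporter_base = cfg.extranuclear_background + profile * (nuclear_bg - cfg.extranuclear_background)

    # sample spots: integer-pixel positions fully inside their nucleus and
    # mutually separated by >= 4 sigma so spot counts stay resolvable
    slo, shi = cfg.spots_per_nucleus_range
    spot_rows = []
    mid = cfg.n_slices // 2
    peak_choices = np.arange(max(0, mid - 1), min(cfg.n_slices, mid + 2))
    for label, (cy, cx, r) in enumerate(nuclei, start=1):
        n_spots = int(rng.integers(slo, shi + 1))
        inner = max(1.0, r - 3 * cfg.spot_sigma)
        positions: list[tuple[int, int]] = []
        for j in range(n_spots):
            for _attempt in range(200):
                ang = rng.uniform(0, 2 * math.pi)
                rad = inner * math.sqrt(rng.uniform())
                sy = int(round(cy + rad * math.sin(ang)))
                sx = int(round(cx + rad * math.cos(ang)))
                if all(
                    math.hypot(sy - py, sx - px) >= 4 * cfg.spot_sigma
                    for py, px in positions
                ):
                    positions.append((sy, sx))
                    break
            else:  # crowded small nucleus: accept the last candidate
                positions.append((sy, sx))
            peak_slice = int(rng.choice(peak_choices))
            spot_rows.append(
                {
                    "nucleus_id": label,
                    "spot_id": len(spot_rows) + 1,
                    "y": positions[-1][0],
                    "x": positions[-1][1],
                    "amplitude": amp,
                    "peak_slice": peak_slice,
                }
            )

    pixels = np.zeros((2, cfg.n_slices, h, w))
    sigma_z = 1.5  # axial extent of a spot, in slices
    for s in range(cfg.n_slices):
        dna = dna_base.copy()
        rep = reporter_base.copy()
        for row in spot_rows:
            axial = math.exp(-((s - row["peak_slice"]) ** 2) / (2 * sigma_z**2))
            _add_gaussian_spot(rep, row["y"], row["x"], row["amplitude"] * axial, cfg.spot_sigma)
        if cfg.noise_sd > 0:
            dna = dna + rng.normal(0.0, cfg.noise_sd, size=dna.shape)
            rep = rep + rng.normal(0.0, cfg.noise_sd, size=rep.shape)
        pixels[0, s] = dna
        pixels[1, s] = rep

    stack = ImageStack(
        pixels=pixels,
        channel_names=("dna", "reporter"),
        pixel_size=cfg.pixel_size,
        slice_step=0.2,
        meta={"preset": condition_preset, "seed": cfg.seed},
    )
    truth = GroundTruth(
        nuclei=pd.DataFrame(
            [
                {"nucleus_id": i + 1, "y": cy, "x": cx, "radius": r}
                for i, (cy, cx, r) in enumerate(nuclei)
            ],
            columns=["nucleus_id", "y", "x", "radius"],
        ),
        spots=pd.DataFrame(
            spot_rows,
            columns=["nucleus_id", "spot_id", "y", "x", "amplitude", "peak_slice"],
        ),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# spot motion
# ---------------------------------------------------------------------------


def simulate_trajectories(cfg: MotionConfig):
    """Sample observed spot trajectories and their truth table.

    Brownian: per-axis increments ~ N(0, 2 D Δt); observed coordinates are
    the true ones plus N(0, σ_loc²) localization noise.  Confined: the same
    increments with the radial excursion from the start reflected at the
    confinement radius.

    Returns ``(trajectories, truth)`` where trajectories is a list of
    :class:`repeatmeth.motility.Trajectory` (coordinates in µm) and
    ``truth.trajectories`` holds the noise-free coordinates.
    """
    from .motility import Trajectory  # local import to avoid a cycle

    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_trajectories, cfg.n_frames
    step_sd = math.sqrt(2 * cfg.diffusion_coefficient * cfg.frame_interval)

    starts = rng.uniform(5.0, 20.0, size=(n, 2))
    steps = rng.normal(0.0, step_sd, size=(n, m - 1, 2)) if step_sd > 0 else np.zeros((n, m - 1, 2))

    true = np.empty((n, m, 2))
    true[:, 0] = starts
    if cfg.motion_model == "brownian":
        true[:, 1:] = starts[:, None, :] + np.cumsum(steps, axis=1)
    else:
        radius = float(cfg.confinement_radius)  # type: ignore[arg-type]
        pos = starts.copy()
        for t in range(1, m):
            pos = pos + steps[:, t - 1]
            disp = pos - starts
            dist = np.hypot(disp[:, 0], disp[:, 1])
            over = dist > radius
            if np.any(over):
                scale = (2 * radius - dist[over]) / dist[over]
                pos[over] = starts[over] + disp[over] * scale[:, None]
            true[:, t] = pos

    observed = true
    if cfg.localization_sd > 0:
        observed = true + rng.normal(0.0, cfg.localization_sd, size=true.shape)

    trajectories = [
        Trajectory(id=i, frame_interval=cfg.frame_interval, coords=observed[i])
        for i in range(n)
    ]
    frames = np.tile(np.arange(m), n)
    truth = GroundTruth(
        trajectories=pd.DataFrame(
            {
                "trajectory_id": np.repeat(np.arange(n), m),
                "frame": frames,
                "t_s": frames * cfg.frame_interval,
                "x_true_um": true[:, :, 0].ravel(),
                "y_true_um": true[:, :, 1].ravel(),
            }
        )
    )
    return trajectories, truth


def render_movie(trajectories: Sequence, cfg: SceneConfig) -> ImageStack:
    """Render trajectories as a single-channel time-lapse movie.

    One frame per time point; each spot becomes a lateral Gaussian of
    ``cfg.spot_sigma`` and peak ``cfg.spot_amplitude`` on the extranuclear
    background, plus read noise.  Trajectory coordinates (µm) are converted
    to pixels with ``cfg.pixel_size``; a coordinate outside the field is an
    error naming the trajectory and frame.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_height, cfg.image_width
    if trajectories:
        n_frames = len(trajectories[0].coords)
        interval = trajectories[0].frame_interval
        for traj in trajectories:
            if len(traj.coords) != n_frames:
                raise ValueError(
                    f"trajectory {traj.id} has {len(traj.coords)} frames, expected {n_frames}"
                )
            px = np.asarray(traj.coords) / cfg.pixel_size
            bad = np.where(
                (px[:, 0] < 0) | (px[:, 0] >= w) | (px[:, 1] < 0) | (px[:, 1] >= h)
            )[0]
            if bad.size:
                raise ValueError(
                    f"trajectory {traj.id} leaves the {h}x{w} px field at frame {bad[0]}"
                )
    else:
        n_frames, interval = 1, 0.1

    frames = np.full((1, n_frames, h, w), float(cfg.extranuclear_background))
    for traj in trajectories:
        px = np.asarray(traj.coords) / cfg.pixel_size
        for t in range(n_frames):
            # trajectory coords are (x, y) µm -> image (y, x) px
            _add_gaussian_spot(
                frames[0, t], px[t, 1], px[t, 0], cfg.spot_amplitude, cfg.spot_sigma
            )
    if cfg.noise_sd > 0:
        frames += rng.normal(0.0, cfg.noise_sd, size=frames.shape)

    return ImageStack(
        pixels=frames,
        channel_names=("reporter",),
        pixel_size=cfg.pixel_size,
        frame_interval=interval,
        meta={"n_trajectories": len(trajectories)},
    )


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------


def _ct_delay(fraction: float, efficiency: float, per_site_count: int | None) -> float:
    """Cycles of delay caused by digesting the unprotected template fraction."""
    amplifiable = fraction if per_site_count is None else fraction**per_site_count
    if amplifiable <= 0:
        return math.inf
    return -math.log(amplifiable) / math.log(efficiency)


def simulate_qpcr_plate(cfg: QPCRSimConfig) -> pd.DataFrame:
    """Simulate Ct values for an MSRE-qPCR (and optional RT-qPCR) plate.

    Returns a tidy table with columns ``sample_id, condition,
    biological_repeat, primer_role, technical_replicate, ct``.  Fully
    digested samples (methylated fraction 0) carry an undetermined-Ct
    sentinel (NaN) in their ``msre_target`` rows.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for rep in range(1, cfg.n_biological + 1):
        for name, frac, fold in cfg.conditions:
            sample = f"{name}_r{rep}"
            input_shift = rng.normal(0.0, cfg.biological_sd) if cfg.biological_sd > 0 else 0.0
            base = cfg.ct_baseline + input_shift
            delay = _ct_delay(frac, cfg.efficiency, cfg.per_site_count)

            role_means = {"msre_control": base, "msre_target": base + delay}
            if cfg.include_expression:
                ref = cfg.expr_reference_baseline + input_shift
                expr_delay = (
                    math.inf if fold <= 0 else -math.log(fold) / math.log(cfg.efficiency)
                )
                role_means["expr_reference"] = ref
                role_means["expr_target"] = ref + cfg.expr_target_offset + expr_delay

            for role, mean_ct in role_means.items():
                for tech in range(1, cfg.n_technical + 1):
                    if math.isinf(mean_ct):
                        ct = UNDETERMINED_CT
                    else:
                        ct = mean_ct + (
                            rng.normal(0.0, cfg.technical_sd) if cfg.technical_sd > 0 else 0.0
                        )
                    rows.append(
                        {
                            "sample_id": sample,
                            "condition": name,
                            "biological_repeat": rep,
                            "primer_role": role,
                            "technical_replicate": tech,
                            "ct": ct,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------


def simulate_flow_population(
    cfg: FlowSimConfig, shift_factor: float = 1.0, sample_id: str = "sample"
) -> pd.DataFrame:
    """Simulate a reporter-positive flow sample and its paired parental control.

    The positive population is log-normal, multiplied by ``shift_factor``
    (so the population median scales by exactly that factor); a
    ``negative_fraction`` of events comes from a dimmer autofluorescence
    component.  The parental control contains only the negative component
    with the same event count.

    Returns a tidy table with columns ``sample_id, intensity``, containing
    ``sample_id`` and ``"parental_control"`` rows.
    """
    cfg.validate()
    if shift_factor <= 0:
        raise ValueError("shift_factor must be > 0")
    rng = np.random.default_rng(cfg.seed)

    n_neg = int(round(cfg.negative_fraction * cfg.n_events))
    n_pos = cfg.n_events - n_neg
    positive = shift_factor * np.exp(rng.normal(cfg.log_mean, cfg.log_sd, size=n_pos))
    negative = np.exp(rng.normal(cfg.negative_log_mean, cfg.negative_log_sd, size=n_neg))
    control = np.exp(rng.normal(cfg.negative_log_mean, cfg.negative_log_sd, size=cfg.n_events))

    return pd.DataFrame(
        {
            "sample_id": [sample_id] * cfg.n_events + ["parental_control"] * cfg.n_events,
            "intensity": np.concatenate([positive, negative, control]),
        }
    )


# ---------------------------------------------------------------------------
# molecular fixtures
# ---------------------------------------------------------------------------


def build_msre_amplicon(n_sites: int = 6, length: int = 200, seed: int = 0):
    """Construct a synthetic amplicon carrying exactly ``n_sites`` CCGC sites.

    The backbone is random DNA scrubbed of CCGC/GCGG on both strands, with
    the sites written in at evenly spaced interior positions; the first and
    last 20 bases serve as primers.  Returns a
    :class:`repeatmeth.qpcr.AmpliconSpec`.  Synthetic stand-in sequence, not
    a genomic one.
    """
    from .qpcr import AmpliconSpec, count_enzyme_sites, reverse_complement

    if length < 60 + 4 * n_sites:
        raise ValueError("amplicon too short for the requested site count")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    for _attempt in range(200):
        seq = list(rng.choice(bases, size=length))
        # scrub accidental sites on either strand
        s = "".join(seq)
        while "CCGC" in s or "GCGG" in s:
            i = max(s.find("CCGC"), s.find("GCGG"))
            seq[i] = str(rng.choice(bases))
            s = "".join(seq)
        # write sites into the interior, clear of the primer regions
        usable = length - 50 - 4
        for k in range(n_sites):
            pos = 25 + (k * usable) // max(1, n_sites - 1) if n_sites > 1 else 25 + usable // 2
            seq[pos : pos + 4] = list("CCGC")
        s = "".join(seq)
        if count_enzyme_sites(s, "CCGC", count_both_strands=True) == n_sites and "TCTAGA" not in s:
            spec = AmpliconSpec(
                name=f"synthetic_msre_{n_sites}site",
                sequence=s,
                forward_primer=s[:20],
                reverse_primer=reverse_complement(s[-20:]),
                enzyme_motifs=("CCGC",),
            )
            return spec
    raise RuntimeError("failed to construct a clean synthetic amplicon")
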
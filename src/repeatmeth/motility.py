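"""Chromatin-mobility analysis from live-cell spot imaging.

Pipeline: temporal moving average over adjacent frames, per-frame spot
detection, greedy nearest-neighbour frame-to-frame linking, mean square
displacement

    MSD(τ) = ⟨ |r(t) − r(t+τ)|² ⟩,

with the average taken over both time origins t (overlapping windows, all
ordered pairs within a trajectory) and, for the ensemble profile, over all
tracked trajectories.  Per-trajectory mobility is summarised at a short lag
(default 1 s) and outliers are removed with the scaled-MAD rule (more than
three scaled median absolute deviations from the median).

All MSD values are in µm²; pixel→µm conversion is mandatory at trajectory
construction and never implicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max

from .stacks import ImageStack

__all__ = [
    "Trajectory",
    "MSDProfile",
    "MobilitySummary",
    "DiffusionFit",
    "temporal_moving_average",
    "detect_spots",
    "track_spots",
    "compute_msd",
    "scaled_mad_filter",
    "mobility_summary",
    "fit_diffusion",
    "trajectories_to_frame",
    "frame_to_trajectories",
]

#: Scale factor that makes the MAD a consistent estimator of the standard
#: deviation under normality.
MAD_SCALE = 1.4826


@dataclass
class Trajectory:
    """2-D spot coordinates over uniformly spaced time points.

    ``coords`` is an ``(n, 2)`` array of (x, y) positions in µm; time of
    point i is ``i * frame_interval`` seconds (plus an arbitrary origin).
    """

    id: int | str
    frame_interval: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if len(self.coords) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class MSDProfile:
    """MSD(τ) with pair counts; lags are strictly increasing multiples of Δt."""

    trajectory_id: int | str
    lags: np.ndarray  # s
    msd: np.ndarray  # µm²
    n_pairs: np.ndarray

    def msd_at(self, lag: float, atol: float = 1e-9) -> float:
        idx = np.where(np.isclose(self.lags, lag, atol=atol))[0]
        if idx.size == 0:
            raise KeyError(f"lag {lag} s not present in profile")
        return float(self.msd[idx[0]])


@dataclass
class MobilitySummary:
    """Per-trajectory mobility scores plus exclusion bookkeeping."""

    scores: pd.DataFrame  # trajectory_id, msd_at_lag, msd_mean_to_lag, outlier
    lag_target: float
    n_excluded_short: int = 0


@dataclass
class DiffusionFit:
    """Least-squares line through (τ, MSD): D = slope/4, offset = intercept."""

    diffusion_coefficient: float  # µm²/s
    offset: float  # µm²; ≈ 4 σ_loc² for pure localization noise
    negative_d: bool = False


# ---------------------------------------------------------------------------
# movie preprocessing and detection
# ---------------------------------------------------------------------------


def temporal_moving_average(movie: ImageStack, window: int = 5) -> ImageStack:
    """Trailing moving average over ``window`` adjacent frames.

    Output frame t is the mean of input frames t … t+window−1, so the result
    has ``N − window + 1`` frames; the time origin shift is recorded in the
    stack metadata.
    """
    n = movie.n_planes
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    pixels = movie.pixels
    if window == 1:
        averaged = pixels.copy()
    else:
        csum = np.cumsum(pixels, axis=1)
        csum = np.concatenate([np.zeros_like(csum[:, :1]), csum], axis=1)
        averaged = (csum[:, window:] - csum[:, :-window]) / window
    meta = dict(movie.meta)
    meta["moving_average_window"] = window
    meta["time_origin_shift_frames"] = 0  # trailing: output t aligns to input t
    return ImageStack(
        pixels=averaged,
        channel_names=movie.channel_names,
        pixel_size=movie.pixel_size,
        frame_interval=movie.frame_interval,
        slice_step=movie.slice_step,
        meta=meta,
    )


def detect_spots(
    movie: ImageStack,
    channel: int | str = 0,
    threshold_abs: float | None = None,
    min_distance: int = 3,
) -> pd.DataFrame:
    """Per-frame local-maximum spot detection.

    ``threshold_abs`` defaults to the frame median plus half the frame peak
    range — adequate for the high-contrast synthetic movies this package
    generates.  Returns a table with columns ``frame, y, x`` (pixels).
    """
    frames = movie.channel(channel)
    rows = []
    for t in range(frames.shape[0]):
        img = frames[t]
        thr = threshold_abs
        if thr is None:
            thr = float(np.median(img) + 0.5 * (img.max() - np.median(img)))
        peaks = peak_local_max(img, min_distance=min_distance, threshold_abs=thr)
        for y, x in peaks:
            rows.append({"frame": t, "y": float(y), "x": float(x)})
    return pd.DataFrame(rows, columns=["frame", "y", "x"])


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


def track_spots(
    detections: pd.DataFrame,
    max_displacement: float,
    min_length: int = 2,
    pixel_size: float = 1.0,
    frame_interval: float = 0.1,
) -> list[Trajectory]:
    """Greedy nearest-neighbour frame-to-frame linking.

    Candidate links between consecutive frames are sorted by distance and
    assigned greedily under ``max_displacement`` (µm), which resolves
    crossings by minimal displacement; remaining ties break deterministically
    by detection order.  There is no gap closing: a spot missing in one frame
    terminates its trajectory.  Trajectories shorter than ``min_length``
    frames are discarded.  Detections are given in pixels (columns ``frame,
    y, x``) and converted to µm with ``pixel_size``.
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    if detections.empty:
        return []
    det = detections.sort_values(["frame"], kind="stable").reset_index(drop=True)
    det_xy = det[["x", "y"]].to_numpy(dtype=float) * pixel_size

    active: list[dict] = []  # {points: [...], last_frame}
    finished: list[list[np.ndarray]] = []
    for frame in range(int(det["frame"].min()), int(det["frame"].max()) + 1):
        idx = np.where(det["frame"].to_numpy() == frame)[0]
        points = det_xy[idx]
        live = [tr for tr in active if tr["last_frame"] == frame - 1]
        stale = [tr for tr in active if tr["last_frame"] < frame - 1]
        finished.extend(tr["points"] for tr in stale)

        links = []
        for ti, tr in enumerate(live):
            last = tr["points"][-1]
            for di in range(len(points)):
                d = math.hypot(*(points[di] - last))
                if d <= max_displacement:
                    links.append((d, ti, di))
        links.sort(key=lambda t: (t[0], t[1], t[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for d, ti, di in links:
            if ti in used_tracks or di in used_dets:
                continue
            live[ti]["points"].append(points[di])
            live[ti]["last_frame"] = frame
            used_tracks.add(ti)
            used_dets.add(di)

        unmatched_tracks = [tr for ti, tr in enumerate(live) if ti not in used_tracks]
        finished.extend(tr["points"] for tr in unmatched_tracks)
        active = [tr for ti, tr in enumerate(live) if ti in used_tracks]
        for di in range(len(points)):
            if di not in used_dets:
                active.append({"points": [points[di]], "last_frame": frame})
    finished.extend(tr["points"] for tr in active)

    trajectories = []
    for pts in finished:
        if len(pts) >= max(2, min_length):
            trajectories.append(
                Trajectory(
                    id=len(trajectories),
                    frame_interval=frame_interval,
                    coords=np.asarray(pts),
                )
            )
    return trajectories


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------


def _msd_sums(coords: np.ndarray, max_k: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum of squared displacements and pair count per lag index 1..max_k."""
    sums = np.empty(max_k)
    counts = np.empty(max_k, dtype=int)
    for k in range(1, max_k + 1):
        disp = coords[k:] - coords[:-k]
        sums[k - 1] = np.sum(disp[:, 0] ** 2 + disp[:, 1] ** 2)
        counts[k - 1] = len(disp)
    return sums, counts


def compute_msd(
    trajectories: list[Trajectory] | Trajectory,
    max_lag: float | None = None,
    mode: str = "ensemble",
):
    """MSD over all ordered pairs (t, t+τ), per trajectory or pooled.

    Lags are τ = k·Δt up to ``max_lag`` (default: the longest computable
    lag).  ``mode='per_trajectory'`` returns one :class:`MSDProfile` per
    trajectory; ``mode='ensemble'`` additionally averages over trajectories,
    weighting each lag by its pair count.  Lags with zero pairs are omitted,
    never reported as 0.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("no trajectories given")
    if mode not in ("per_trajectory", "ensemble"):
        raise ValueError("mode must be 'per_trajectory' or 'ensemble'")
    dt = trajectories[0].frame_interval
    if not all(math.isclose(tr.frame_interval, dt) for tr in trajectories):
        raise ValueError("all trajectories must share the frame interval")

    longest = max(len(tr) for tr in trajectories) - 1
    max_k = longest if max_lag is None else min(longest, int(round(max_lag / dt)))
    if max_k < 1:
        raise ValueError("max_lag shorter than one frame interval")

    profiles = []
    pooled_sums = np.zeros(max_k)
    pooled_counts = np.zeros(max_k, dtype=int)
    for tr in trajectories:
        k_tr = min(max_k, len(tr) - 1)
        sums, counts = _msd_sums(tr.coords, k_tr)
        pooled_sums[:k_tr] += sums
        pooled_counts[:k_tr] += counts
        profiles.append(
            MSDProfile(
                trajectory_id=tr.id,
                lags=dt * np.arange(1, k_tr + 1),
                msd=sums / counts,
                n_pairs=counts,
            )
        )
    if mode == "per_trajectory":
        return profiles
    has_pairs = pooled_counts > 0
    return MSDProfile(
        trajectory_id="ensemble",
        lags=dt * np.arange(1, max_k + 1)[has_pairs],
        msd=pooled_sums[has_pairs] / pooled_counts[has_pairs],
        n_pairs=pooled_counts[has_pairs],
    )


# ---------------------------------------------------------------------------
# outlier filtering and summaries
# ---------------------------------------------------------------------------


def scaled_mad_filter(values) -> tuple[np.ndarray, np.ndarray]:
    """Flag values more than three scaled MADs from the median.

    scaled MAD = 1.4826 · median(|x − median(x)|).  If the scaled MAD is
    zero (over half the values identical), any value different from the
    median is flagged — the documented degenerate rule.  Returns
    ``(kept_values, outlier_flags)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("scaled_mad_filter needs at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("scaled_mad_filter requires finite values")
    med = np.median(x)
    smad = MAD_SCALE * np.median(np.abs(x - med))
    if smad == 0:
        flags = x != med
    else:
        flags = np.abs(x - med) > 3 * smad
    return x[~flags], flags


def mobility_summary(
    profiles: list[MSDProfile],
    lag_target: float = 1.0,
    apply_outlier_filter: bool = True,
) -> MobilitySummary:
    """Summarise per-trajectory mobility at a short lag.

    For every trajectory whose profile reaches ``lag_target`` the summary
    reports both the MSD value at the target lag and the mean MSD over all
    lags up to it (two readings of a short-lag mobility index; comparisons
    default to the value at the lag).  Trajectories too short to reach the
    target lag are excluded and counted.  The scaled-MAD rule flags outliers
    on the at-lag score before any aggregation.
    """
    rows = []
    n_excluded = 0
    for p in profiles:
        within = p.lags <= lag_target + 1e-9
        at = np.isclose(p.lags, lag_target, atol=1e-9)
        if not at.any():
            n_excluded += 1
            continue
        rows.append(
            {
                "trajectory_id": p.trajectory_id,
                "msd_at_lag": float(p.msd[at][0]),
                "msd_mean_to_lag": float(p.msd[within].mean()),
            }
        )
    scores = pd.DataFrame(rows, columns=["trajectory_id", "msd_at_lag", "msd_mean_to_lag"])
    if len(scores) and apply_outlier_filter:
        _, flags = scaled_mad_filter(scores["msd_at_lag"].to_numpy())
        scores["outlier"] = flags
    else:
        scores["outlier"] = pd.Series([], dtype=bool) if not len(scores) else False
    return MobilitySummary(scores=scores, lag_target=lag_target, n_excluded_short=n_excluded)


def fit_diffusion(profile: MSDProfile) -> DiffusionFit:
    """Fit MSD(τ) = 4 D τ + offset by least squares.

    For 2-D Brownian motion with localization noise the expected line is
    ``4 D τ + 4 σ_loc²``.  A negative fitted D is returned as-is with a
    warning flag, never clamped.
    """
    if len(profile.lags) < 2:
        raise ValueError("need at least 2 lags to fit a line")
    slope, intercept = np.polyfit(profile.lags, profile.msd, 1)
    d = slope / 4.0
    return DiffusionFit(diffusion_coefficient=float(d), offset=float(intercept), negative_d=d < 0)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_TRACK_COLUMNS = ["trajectory_id", "frame", "t_s", "x_um", "y_um"]


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into the interchange table (µm coordinates)."""
    rows = []
    for tr in trajectories:
        for i, (x, y) in enumerate(tr.coords):
            rows.append(
                {
                    "trajectory_id": tr.id,
                    "frame": i,
                    "t_s": i * tr.frame_interval,
                    "x_um": x,
                    "y_um": y,
                }
            )
    return pd.DataFrame(rows, columns=_TRACK_COLUMNS)


def frame_to_trajectories(table: pd.DataFrame) -> list[Trajectory]:
    """Rebuild trajectories from the interchange table."""
    missing = [c for c in _TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trajectory table missing columns: {missing}")
    out = []
    for tid, grp in table.groupby("trajectory_id", sort=True):
        grp = grp.sort_values("frame")
        t = grp["t_s"].to_numpy(dtype=float)
        if len(t) >= 2:
            dts = np.diff(t)
            if not np.allclose(dts, dts[0]):
                raise ValueError(f"trajectory {tid}: non-uniform time spacing")
            dt = float(dts[0])
        else:
            raise ValueError(f"trajectory {tid}: fewer than 2 points")
        out.append(
            Trajectory(id=tid, frame_interval=dt, coords=grp[["x_um", "y_um"]].to_numpy())
        )
    return out
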
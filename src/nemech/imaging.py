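"""Fluorescence quantification at the nuclear envelope.

Covers the imaging readouts of the study design: angular ring-intensity
profiles and their coefficient of variation (the LINC "clustering index"),
stage-normalised mean intensities, polarization profiles rotated so the
brightest point sits at 180 degrees, patch tracking with drift correction
and mean speeds, 3D nuclear volume segmentation, and the alignment and
piecewise rate fitting of nuclear-collapse time series.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

__all__ = [
    "RingProfile",
    "PolarizationProfile",
    "Track",
    "CollapseSeries",
    "sample_ring_profile",
    "fit_ring",
    "clustering_index",
    "normalized_mean_intensity",
    "polarization_profile",
    "peak_region_stat",
    "link_tracks",
    "track_mean_speed",
    "mean_speeds",
    "segment_nucleus_volume",
    "align_collapse_series",
    "collapse_rates",
    "fit_piecewise_rates",
]


@dataclass
class RingProfile:
    """Angularly sampled intensity around a nuclear periphery.

    Angles are degrees on a uniform grid in [0, 360), counterclockwise
    from the image +x axis; intensities are background-subtracted and
    floored at zero.
    """

    angles_deg: np.ndarray
    intensity: np.ndarray
    nucleus_id: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.angles_deg.shape != self.intensity.shape:
            raise ValueError("angles and intensity must have equal length")
        steps = np.diff(self.angles_deg)
        if steps.size and not np.allclose(steps, steps[0]):
            raise ValueError("angular grid must be uniform")

    @property
    def step_deg(self) -> float:
        return float(self.angles_deg[1] - self.angles_deg[0])

    def mean_intensity(self) -> float:
        return float(np.mean(self.intensity))


@dataclass
class PolarizationProfile:
    """A ring profile rotated so its brightest point is at 180 degrees and
    scaled so the intensity at 0 degrees equals 1."""

    angles_deg: np.ndarray
    intensity: np.ndarray
    folded: bool = False
    nucleus_id: str = ""


@dataclass
class Track:
    """One linked particle trajectory with per-frame 3D positions (um)."""

    particle_id: int
    frames: np.ndarray
    positions_um: np.ndarray  # (n, 3)
    frame_interval_s: float = 5.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return self.frames.size


@dataclass
class CollapseSeries:
    """A contact-aligned, final-frame-normalised collapse trajectory.

    ``frames`` are re-indexed relative to the NE-SC contact frame (0 at
    contact); both size series are divided by their final-frame value, so
    the normalised sizes are exactly 1 at the last frame.
    """

    frames: np.ndarray
    time_s: np.ndarray
    ne_norm: np.ndarray
    sc_norm: np.ndarray
    contact_index: int
    ne_final_um: float
    sc_final_um: float


# ---------------------------------------------------------------------------
# ring sampling
# ---------------------------------------------------------------------------

def _image_mode(image: np.ndarray, bins: int = 256) -> float:
    """Modal pixel value, used as the background estimate."""
    counts, edges = np.histogram(image.ravel(), bins=bins)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def sample_ring_profile(
    image: np.ndarray,
    center: tuple[float, float],
    radius: float,
    ring_width: float = 3.0,
    angular_step_deg: float = 1.0,
    n_radial: int = 5,
    background: float | None = None,
    nucleus_id: str = "",
    stage: str = "",
) -> RingProfile:
    """Sample mean intensity around a circular periphery.

    ``center`` is (x, y) in pixel coordinates (0-based pixel centres, x
    rightward, y downward).  At each angle the intensity is the mean of
    ``n_radial`` bilinear samples spread across ``ring_width`` radially.
    The background (image mode unless given) is subtracted and the result
    floored at 0.
    """
    cx, cy = center
    ny, nx = image.shape
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError("ring center lies outside the image")
    if radius + ring_width / 2 > min(cx, cy, nx - 1 - cx, ny - 1 - cy):
        raise ValueError("ring extends outside the image")
    if background is None:
        background = _image_mode(image)
    angles = np.arange(0.0, 360.0, angular_step_deg)
    radii = np.linspace(radius - ring_width / 2, radius + ring_width / 2, n_radial)
    theta = np.deg2rad(angles)[None, :]
    rr = radii[:, None]
    xs = cx + rr * np.cos(theta)
    ys = cy - rr * np.sin(theta)  # y grows downward; angles CCW from +x
    samples = ndimage.map_coordinates(
        image.astype(float), np.stack([ys.ravel(), xs.ravel()]), order=1, mode="nearest"
    ).reshape(n_radial, angles.size)
    intensity = np.clip(samples.mean(axis=0) - background, 0.0, None)
    return RingProfile(angles, intensity, nucleus_id=nucleus_id, stage=stage)


def fit_ring(
    image: np.ndarray,
    center0: tuple[float, float],
    radius0: float,
    search_px: int = 3,
    ring_width: float = 3.0,
) -> tuple[tuple[float, float], float]:
    """Refine a ring's centre and radius by maximising mean ring intensity
    over a small integer search grid around the initial guess."""
    best = (-np.inf, center0, radius0)
    offsets = range(-search_px, search_px + 1)
    for dx in offsets:
        for dy in offsets:
            for dr in offsets:
                c = (center0[0] + dx, center0[1] + dy)
                r = radius0 + dr
                if r <= ring_width:
                    continue
                try:
                    prof = sample_ring_profile(image, c, r, ring_width, angular_step_deg=5.0)
                except ValueError:
                    continue
                score = prof.mean_intensity()
                if score > best[0]:
                    best = (score, c, r)
    return best[1], float(best[2])


# ---------------------------------------------------------------------------
# intensity statistics
# ---------------------------------------------------------------------------

def clustering_index(profile: RingProfile | np.ndarray) -> float:
    """Coefficient of variation (sample SD / mean) of peripheral intensity.

    High values indicate patchy ("clustered") LINC-complex distribution;
    the index is invariant to intensity scaling and circular rotation.
    Sample (n-1) SD is used because angular sample counts are modest.
    """
    values = profile.intensity if isinstance(profile, RingProfile) else np.asarray(profile, float)
    mean = float(np.mean(values))
    if mean <= 0:
        raise ValueError("clustering index undefined for non-positive mean intensity")
    return float(np.std(values, ddof=1) / mean)


def normalized_mean_intensity(
    profiles_by_stage: Mapping[str, Sequence[RingProfile | float]],
    reference_stage: str = "TZ",
) -> dict[str, np.ndarray]:
    """Per-nucleus mean ring intensity normalised to the reference stage.

    Each nucleus's mean intensity is divided by the mean over all
    reference-stage nuclei, so the reference group averages 1.
    """
    if reference_stage not in profiles_by_stage or not len(profiles_by_stage[reference_stage]):
        raise ValueError(f"reference stage {reference_stage!r} is empty")

    def _mean(p: RingProfile | float) -> float:
        return p.mean_intensity() if isinstance(p, RingProfile) else float(p)

    ref = float(np.mean([_mean(p) for p in profiles_by_stage[reference_stage]]))
    if ref <= 0:
        raise ValueError("reference stage has non-positive mean intensity")
    return {
        stage: np.asarray([_mean(p) for p in ps], dtype=float) / ref
        for stage, ps in profiles_by_stage.items()
    }


def _circular_smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.full(window, 1.0 / window)
    padded = np.concatenate([values[-window:], values, values[:window]])
    return np.convolve(padded, kernel, mode="same")[window:-window]


def polarization_profile(
    profile: RingProfile, fold: bool = False, smooth_deg: float = 5.0
) -> PolarizationProfile:
    """Rotate a ring profile so the brightest point sits at 180 degrees and
    normalise so the intensity at 0 degrees equals 1.

    The peak is located on a copy smoothed with a circular moving average
    spanning ``smooth_deg`` (raw values are used for the normalisation);
    argmax ties break toward the smallest angle.  With ``fold=True``,
    intensities at theta and 360 - theta are averaged onto [0, 180],
    exploiting the symmetry of a polar cap about its peak.
    """
    intensity = profile.intensity
    if np.all(intensity == 0):
        raise ValueError("all-zero profile cannot be polarised")
    step = profile.step_deg
    window = max(int(round(smooth_deg / step)), 1)
    smoothed = _circular_smooth(intensity, window)
    peak_idx = int(np.argmax(smoothed))  # ties -> smallest angle
    target_idx = int(round(180.0 / step)) % intensity.size
    rotated = np.roll(intensity, target_idx - peak_idx)
    ref = rotated[0]
    if ref <= 0:
        raise ValueError("intensity at 0 degrees is non-positive after rotation")
    normalised = rotated / ref
    angles = profile.angles_deg
    if fold:
        n = intensity.size
        half = target_idx  # index of 180 degrees
        folded = np.empty(half + 1)
        folded[0] = normalised[0]
        folded[half] = normalised[half]
        for i in range(1, half):
            folded[i] = 0.5 * (normalised[i] + normalised[(n - i) % n])
        return PolarizationProfile(
            angles[: half + 1], folded, folded=True, nucleus_id=profile.nucleus_id
        )
    return PolarizationProfile(angles, normalised, folded=False, nucleus_id=profile.nucleus_id)


def peak_region_stat(
    profiles: Iterable[PolarizationProfile], window_deg: tuple[float, float] = (170.0, 190.0)
) -> np.ndarray:
    """Mean normalised intensity over the closed angular window about the
    peak (170-190 degrees by default), one value per nucleus."""
    lo, hi = window_deg
    out = []
    for p in profiles:
        if p.folded:
            # folded profiles cover [0, 180]; the window reflects about 180
            wlo = min(lo, 360.0 - hi)
            mask = (p.angles_deg >= wlo) & (p.angles_deg <= 180.0)
        else:
            mask = (p.angles_deg >= lo) & (p.angles_deg <= hi)
        if not mask.any():
            raise ValueError("angular grid does not cover the peak window")
        out.append(float(np.mean(p.intensity[mask])))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def link_tracks(
    detections: pd.DataFrame,
    max_displacement_um: float,
    reference_drift_um_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0),
    frame_interval_s: float = 5.0,
) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking of 3D detections.

    The common stage drift (``reference_drift_um_per_frame`` times the
    frame index) is subtracted before linking and from the returned
    positions.  Candidate links are assigned in order of increasing
    distance; links longer than ``max_displacement_um`` are not made and
    unmatched detections start new tracks.
    """
    required = {"frame", "x_um", "y_um", "z_um"}
    if not required.issubset(detections.columns):
        raise ValueError(f"detections need columns {sorted(required)}")
    drift = np.asarray(reference_drift_um_per_frame, dtype=float)
    frames = np.sort(detections["frame"].unique())
    if frames.size < 2:
        raise ValueError("need detections in at least 2 frames")

    def corrected(frame: int) -> np.ndarray:
        sub = detections[detections["frame"] == frame]
        return sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float) - frame * drift

    tracks: list[dict] = []
    prev_pts = corrected(frames[0])
    active = []
    for p in prev_pts:
        tracks.append({"frames": [int(frames[0])], "pos": [p]})
        active.append(len(tracks) - 1)

    for f in frames[1:]:
        pts = corrected(int(f))
        ends = np.asarray([tracks[t]["pos"][-1] for t in active]) if active else np.empty((0, 3))
        n_a, n_d = ends.shape[0], pts.shape[0]
        pairs = []
        if n_a and n_d:
            dists = np.linalg.norm(ends[:, None, :] - pts[None, :, :], axis=2)
            order = np.dstack(np.unravel_index(np.argsort(dists, axis=None), dists.shape))[0]
            used_a: set[int] = set()
            used_d: set[int] = set()
            for ia, idd in order:
                if dists[ia, idd] > max_displacement_um:
                    break
                if ia in used_a or idd in used_d:
                    continue
                pairs.append((int(ia), int(idd)))
                used_a.add(int(ia))
                used_d.add(int(idd))
        matched_d = {idd for _, idd in pairs}
        next_active = []
        for ia, idd in pairs:
            t = active[ia]
            tracks[t]["frames"].append(int(f))
            tracks[t]["pos"].append(pts[idd])
            next_active.append(t)
        for idd in range(n_d):
            if idd not in matched_d:
                tracks.append({"frames": [int(f)], "pos": [pts[idd]]})
                next_active.append(len(tracks) - 1)
        active = next_active

    return [
        Track(i, t["frames"], np.asarray(t["pos"]), frame_interval_s)
        for i, t in enumerate(tracks)
    ]


def track_mean_speed(track: Track) -> float:
    """Mean 3D speed (um/s) over a track's consecutive positions."""
    if len(track) < 2:
        raise ValueError("mean speed undefined for a singleton track")
    disp = np.linalg.norm(np.diff(track.positions_um, axis=0), axis=1)
    dt = np.diff(track.frames) * track.frame_interval_s
    return float(np.mean(disp / dt))


def mean_speeds(tracks: Iterable[Track]) -> np.ndarray:
    """Mean speeds of all non-singleton tracks."""
    return np.asarray([track_mean_speed(t) for t in tracks if len(t) >= 2])


# ---------------------------------------------------------------------------
# volume segmentation
# ---------------------------------------------------------------------------

def segment_nucleus_volume(
    stack: np.ndarray,
    threshold_method: str = "otsu",
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> pd.DataFrame:
    """Segment nuclei in a 3D stack and report their volumes.

    Otsu (or a fixed ``threshold_method=float``) thresholding followed by
    26-connected component labelling; volume is voxel count times voxel
    volume.  Components touching the stack boundary are flagged, since
    their volumes are lower bounds.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3D stack (z, y, x)")
    if isinstance(threshold_method, (int, float)):
        thr = float(threshold_method)
    elif threshold_method == "otsu":
        if np.all(stack == stack.flat[0]):
            return pd.DataFrame(columns=["label", "volume_um3", "touches_boundary"])
        thr = float(threshold_otsu(stack))
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    mask = stack > thr
    if not mask.any():
        return pd.DataFrame(columns=["label", "volume_um3", "touches_boundary"])
    labels = cc_label(mask, connectivity=3)
    voxel_vol = float(np.prod(voxel_size_um))
    rows = []
    for rp in regionprops(labels):
        zmin, ymin, xmin, zmax, ymax, xmax = rp.bbox
        touches = (
            zmin == 0 or ymin == 0 or xmin == 0
            or zmax == stack.shape[0] or ymax == stack.shape[1] or xmax == stack.shape[2]
        )
        rows.append(
            {"label": rp.label, "volume_um3": rp.num_pixels * voxel_vol, "touches_boundary": touches}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# collapse dynamics
# ---------------------------------------------------------------------------

def align_collapse_series(
    ne_size: np.ndarray,
    sc_size: np.ndarray,
    frame_interval_s: float = 10.0,
    contact_tol: float = 1e-6,
    refine: bool = True,
) -> CollapseSeries:
    """Align a collapse trajectory on NE-SC contact and normalise sizes.

    The contact frame is the first frame where ``ne_size - sc_size <=
    contact_tol``.  Under noise a positive tolerance makes that first
    crossing systematically early, so with ``refine=True`` the frames up
    to the crossing (which are all pre-contact) are fit with a line and
    the contact frame is moved to the line's zero crossing, provided that
    extrapolation stays plausibly close (within half the crossing index);
    otherwise the raw crossing is kept.  Frames are re-indexed so contact
    is frame 0 and both series are divided by their final-frame values
    (so the last normalised value is exactly 1).
    """
    ne = np.asarray(ne_size, dtype=float)
    sc = np.asarray(sc_size, dtype=float)
    if ne.shape != sc.shape or ne.ndim != 1:
        raise ValueError("NE and SC series must be 1D and equal length")
    if ne.size < 4:
        raise ValueError("need at least 4 frames")
    gap = ne - sc
    hits = np.flatnonzero(gap <= contact_tol)
    if hits.size == 0:
        raise ValueError(
            f"no NE-SC contact found: minimum separation {float(np.min(gap)):.3g} "
            f"exceeds tol {contact_tol:.3g}"
        )
    contact = int(hits[0])
    if refine and contact >= 3:
        slope, intercept = np.polyfit(np.arange(contact + 1), gap[: contact + 1], 1)
        if slope < 0:
            zero = -intercept / slope
            if contact - 1 <= zero <= min(ne.size - 2, 1.5 * contact):
                contact = int(round(zero))
    if ne[-1] <= 0 or sc[-1] <= 0:
        raise ValueError("final-frame sizes must be positive for normalisation")
    frames = np.arange(ne.size) - contact
    return CollapseSeries(
        frames=frames,
        time_s=frames * frame_interval_s,
        ne_norm=ne / ne[-1],
        sc_norm=sc / sc[-1],
        contact_index=contact,
        ne_final_um=float(ne[-1]),
        sc_final_um=float(sc[-1]),
    )


def fit_piecewise_rates(
    values: np.ndarray, frames: np.ndarray, contact_idx: int, min_frames: int = 2
) -> tuple[float | None, float | None]:
    """OLS slopes (per frame) of ``values`` before and after contact.

    The contact sample is included in both fits.  A side with fewer than
    ``min_frames`` samples yields ``None``.
    """
    values = np.asarray(values, dtype=float)
    frames = np.asarray(frames, dtype=float)
    pre_v, pre_f = values[: contact_idx + 1], frames[: contact_idx + 1]
    post_v, post_f = values[contact_idx:], frames[contact_idx:]

    def slope(f: np.ndarray, v: np.ndarray) -> float | None:
        if f.size < min_frames:
            return None
        return float(np.polyfit(f, v, 1)[0])

    return slope(pre_f, pre_v), slope(post_f, post_v)


def collapse_rates(series: CollapseSeries, min_frames: int = 2) -> tuple[float | None, float | None]:
    """Pre- and post-contact shrinkage rates of the normalised NE size.

    Ordinary least-squares slopes per frame, fit separately on the frames
    up to and from the contact frame.
    """
    contact_idx = int(np.flatnonzero(series.frames == 0)[0])
    return fit_piecewise_rates(series.ne_norm, series.frames, contact_idx, min_frames)
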
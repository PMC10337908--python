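"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here: mechano-NPS
current traces with sizing/node/contraction sub-pulses, nuclear-envelope
ring images with patchy (von Mises) and polarised (cap) intensity,
nuclear-collapse time series in which the envelope shrinks onto the
synaptonemal complex, gonad layouts with zone-dependent collapse fractions,
and particle-detection tables for track linking.  All generators take an
explicit integer seed and are byte-reproducible; no global random state is
touched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nps import ChannelGeometry, CurrentTrace, applied_strain, relative_blockade

__all__ = [
    "ParticleSpec",
    "RingSpec",
    "CollapseSpec",
    "LayoutSpec",
    "DEFAULT_NUCLEUS_DIAMETER_UM",
    "nucleus_population",
    "bead_population",
    "simulate_nps_trace",
    "simulate_ring_image",
    "simulate_collapse_series",
    "simulate_gonad_layout",
    "simulate_tracks",
]

#: Mean diameter (um) of the simulated meiotic-nucleus population.  Chosen
#: so that the average applied strain in the default 2.9-um contraction
#: channel is 0.15, the operating point of the nuclear-stiffness assay.
DEFAULT_NUCLEUS_DIAMETER_UM = 3.41


@dataclass(frozen=True)
class ParticleSpec:
    """One particle (nucleus or calibration bead) transiting the channel.

    ``softness`` is a dimensionless deformability: 0 is rigid, larger
    values clear the contraction segment faster.  It carries the
    ground-truth stiffness ordering that the wCDI must recover.
    """

    diameter_um: float
    softness: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.softness < 0:
            raise ValueError("softness must be >= 0")


@dataclass(frozen=True)
class RingSpec:
    """A fluorescent nuclear-envelope ring with patches and a polar cap.

    The angular intensity is ``base + patches + cap``: ``n_patches`` von
    Mises bumps of height ``patch_amplitude`` and concentration
    ``patch_concentration`` at random angles, plus one cap of height
    ``cap_amplitude`` at ``cap_angle``.  Angles are degrees in [0, 360),
    counterclockwise from the image +x axis.
    """

    radius_px: float
    ring_width_px: float = 3.0
    base_intensity: float = 100.0
    n_patches: int = 0
    patch_concentration: float = 8.0
    patch_amplitude: float = 100.0
    cap_amplitude: float = 0.0
    cap_angle_deg: float = 180.0
    cap_concentration: float = 4.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_px <= self.ring_width_px / 2:
            raise ValueError("radius must exceed half the ring width")
        if min(self.base_intensity, self.patch_amplitude, self.cap_amplitude) < 0:
            raise ValueError("intensities must be non-negative")
        if self.patch_concentration < 0 or self.cap_concentration < 0:
            raise ValueError("von Mises concentrations must be >= 0")
        if not 0 <= self.cap_angle_deg < 360:
            raise ValueError("cap angle must be in [0, 360)")


@dataclass(frozen=True)
class CollapseSpec:
    """Time-lapse of a collapsing nucleus: envelope (NE) and SC sizes.

    Rates are signed size increments per frame (shrinkage is negative).
    The NE shrinks at ``rate_pre`` until ``contact_frame`` and at
    ``rate_post`` afterwards; the SC is constant until contact and then
    shrinks at ``sc_rate_post``.  The default instance makes the NE meet
    the SC exactly at the contact frame.  ``frame_interval_s`` defaults to
    the 10-s cadence used for collapse imaging.
    """

    ne_size0_um: float = 4.0
    sc_size0_um: float = 3.0
    contact_frame: int = 20
    rate_pre: float = -0.05
    rate_post: float = -0.08
    sc_rate_post: float = -0.06
    frame_interval_s: float = 10.0
    n_frames: int = 40
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.ne_size0_um > self.sc_size0_um > 0:
            raise ValueError("require ne_size0 > sc_size0 > 0")
        if not 0 < self.contact_frame < self.n_frames:
            raise ValueError("contact_frame must lie strictly inside the series")


@dataclass(frozen=True)
class LayoutSpec:
    """A gonad axis populated with nuclei whose collapse odds vary by zone.

    The axis runs distal (0) to proximal (``gonad_length``) and is divided
    into ``len(zone_collapse_probs)`` equal-length zones; each nucleus's
    collapsed flag is Bernoulli with its zone's probability.
    ``stage_boundaries`` are the axial positions separating the meiotic
    stage labels.  Three animals per condition is the default replication.
    """

    gonad_length: float = 60.0
    n_nuclei: int = 300
    zone_collapse_probs: tuple[float, ...] = (0.0, 0.0, 0.0, 0.2, 0.6, 0.9)
    stage_boundaries: tuple[float, ...] = (15.0, 35.0, 50.0)
    stage_labels: tuple[str, ...] = ("TZ", "MP", "LP", "Dip")
    n_animals: int = 3
    zone_pairing_probs: tuple[float, ...] | None = None
    zone_synapsis_probs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.zone_collapse_probs):
            raise ValueError("zone probabilities must be in [0, 1]")
        b = self.stage_boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)) or (
            b and (b[0] <= 0 or b[-1] >= self.gonad_length)
        ):
            raise ValueError("stage boundaries must be strictly increasing within (0, L)")
        if len(self.stage_labels) != len(b) + 1:
            raise ValueError("need one more stage label than boundaries")


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

def nucleus_population(
    n: int,
    softness: float,
    mean_diameter_um: float = DEFAULT_NUCLEUS_DIAMETER_UM,
    sd_diameter_um: float = 0.25,
    label: str = "",
    seed: int = 0,
) -> list[ParticleSpec]:
    """Draw a meiotic-nucleus population with Gaussian diameter spread."""
    rng = np.random.default_rng(seed)
    diameters = rng.normal(mean_diameter_um, sd_diameter_um, size=n)
    diameters = np.clip(diameters, 0.5, None)
    return [ParticleSpec(float(d), softness, label) for d in diameters]


def bead_population(
    n: int,
    mean_diameter_um: float = 2.0,
    sd_diameter_um: float = 0.05,
    seed: int = 0,
) -> list[ParticleSpec]:
    """Rigid polystyrene calibration beads, nominally 2 +/- 0.05 um."""
    rng = np.random.default_rng(seed)
    diameters = rng.normal(mean_diameter_um, sd_diameter_um, size=n)
    return [ParticleSpec(float(d), 0.0, "bead") for d in diameters]


# ---------------------------------------------------------------------------
# NPS trace
# ---------------------------------------------------------------------------

#: Fractional contraction slow-down of a rigid particle at unit strain.
RIGID_SLOWDOWN = 2.0


def transit_times(
    particle: ParticleSpec,
    geometry: ChannelGeometry,
    flow_speed_um_s: float,
    slowdown: float = RIGID_SLOWDOWN,
) -> tuple[float, float, float]:
    """Ground-truth (t_s, t_node, t_c) for one particle.

    The sizing and node segments are traversed at the carrier flow speed.
    In the contraction segment a strained particle is slowed by friction
    against the walls; a stiff particle resists deformation and is slowed
    the most, so ``t_c = (L_c / v) * (1 + slowdown * strain / (1 + softness))``.
    Softness strictly shortens ``t_c`` toward the unstrained transit time,
    and an unstrained particle (``d <= w_c``) is not slowed at all.
    """
    v = flow_speed_um_s
    eps = applied_strain(particle.diameter_um, geometry)
    t_s = geometry.sizing_length_um / v
    t_node = geometry.node_length_um / v
    t_c = (geometry.contraction_length_um / v) * (
        1.0 + slowdown * eps / (1.0 + particle.softness)
    )
    return t_s, t_node, t_c


def simulate_nps_trace(
    geometry: ChannelGeometry,
    particles: list[ParticleSpec],
    flow_speed_um_s: float = 10_000.0,
    sampling_rate_hz: float = 50_000.0,
    noise_sd_na: float = 0.005,
    seed: int = 0,
    baseline_na: float = 100.0,
    start_times_s: list[float] | None = None,
    margin_s: float = 0.05,
) -> tuple[CurrentTrace, pd.DataFrame]:
    """Simulate a current trace of particles transiting the channel.

    Each particle contributes, in sequence, a rectangular sizing sub-pulse
    of depth ``dI_s`` and duration ``t_s = L_s / v``, a shallow node
    recovery toward baseline, and a deeper contraction sub-pulse of
    duration ``t_c`` that lengthens with stiffness.  Sub-pulse depths come
    from the same resistive-pulse relation the analyser inverts
    (:func:`nemech.nps.relative_blockade`).  i.i.d. Gaussian noise of sd
    ``noise_sd_na`` is added.

    Events are placed sequentially with a gap of one event duration unless
    ``start_times_s`` is given, in which case overlap is rejected.

    Returns the trace and a ground-truth table with per-particle
    ``dI_s_na``, ``t_s_s``, ``t_c_s``, ``d_um``, ``strain``, ``softness``
    and event start times.
    """
    if flow_speed_um_s <= 0 or sampling_rate_hz <= 0:
        raise ValueError("flow speed and sampling rate must be positive")
    w_s = geometry.sizing_width_um
    for p in particles:
        if p.diameter_um >= w_s:
            raise ValueError(
                f"particle diameter {p.diameter_um:.3g} um >= sizing width {w_s:.3g} um"
            )

    rng = np.random.default_rng(seed)
    rows = []
    durations = []
    for p in particles:
        t_s, t_node, t_c = transit_times(p, geometry, flow_speed_um_s)
        shortest = min(t_s, t_c)
        if shortest * sampling_rate_hz < 20:
            raise ValueError(
                "sampling rate too low: shortest sub-pulse spans "
                f"{shortest * sampling_rate_hz:.1f} < 20 samples"
            )
        durations.append(t_s + t_node + t_c)
        rows.append((p, t_s, t_node, t_c))

    if start_times_s is None:
        starts = []
        t = margin_s
        for dur in durations:
            starts.append(t)
            t += 2.0 * dur
    else:
        if len(start_times_s) != len(particles):
            raise ValueError("need one start time per particle")
        starts = list(start_times_s)
        order = np.argsort(starts)
        for a, b in zip(order[:-1], order[1:]):
            if starts[a] + durations[a] > starts[b]:
                raise ValueError(
                    f"events at t={starts[a]:.4g}s and t={starts[b]:.4g}s overlap; "
                    "increase particle spacing"
                )

    total = (max(s + d for s, d in zip(starts, durations)) if particles else 0.0) + margin_s
    n_samples = max(int(round(total * sampling_rate_hz)), 100)
    time = np.arange(n_samples) / sampling_rate_hz
    current = np.full(n_samples, baseline_na)

    truth_rows = []
    for (p, t_s, t_node, t_c), start in zip(rows, starts):
        dI_s = baseline_na * relative_blockade(p.diameter_um, geometry, "sizing")
        dI_c = baseline_na * relative_blockade(p.diameter_um, geometry, "contraction")
        # the wide node recovers the current nearly to baseline: the
        # residual blockade scales with the node's large effective
        # diameter and the full sensing length, not the short segment
        l_total = (
            geometry.sizing_length_um + geometry.node_length_um + geometry.contraction_length_um
        )
        dI_node = baseline_na * (
            p.diameter_um**3 / (geometry.effective_diameter_um("node") ** 2 * l_total)
        )
        i0 = int(round(start * sampling_rate_hz))
        i1 = i0 + int(round(t_s * sampling_rate_hz))
        i2 = i1 + int(round(t_node * sampling_rate_hz))
        i3 = i2 + int(round(t_c * sampling_rate_hz))
        current[i0:i1] -= dI_s
        current[i1:i2] -= dI_node
        current[i2:i3] -= dI_c
        truth_rows.append(
            {
                "start_s": start,
                "dI_s_na": dI_s,
                "dI_c_na": dI_c,
                "t_s_s": t_s,
                "t_c_s": t_c,
                "d_um": p.diameter_um,
                "strain": applied_strain(p.diameter_um, geometry),
                "softness": p.softness,
                "label": p.label,
            }
        )

    if noise_sd_na > 0:
        current = current + rng.normal(0.0, noise_sd_na, size=n_samples)
    trace = CurrentTrace(time, current, sampling_rate_hz, baseline_na=None)
    return trace, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# ring images
# ---------------------------------------------------------------------------

def _vonmises_bump(theta_rad: np.ndarray, mu_rad: float, kappa: float) -> np.ndarray:
    # unit-peak von Mises bump; kappa 0 -> constant 1
    return np.exp(kappa * (np.cos(theta_rad - mu_rad) - 1.0))


def ring_profile_truth(spec: RingSpec, patch_angles_deg: np.ndarray) -> np.ndarray:
    """Ground-truth angular intensity on a 1-degree grid [0, 360)."""
    theta = np.deg2rad(np.arange(360.0))
    prof = np.full(360, float(spec.base_intensity))
    for a in patch_angles_deg:
        prof += spec.patch_amplitude * _vonmises_bump(
            theta, math.radians(a), spec.patch_concentration
        )
    if spec.cap_amplitude > 0:
        prof += spec.cap_amplitude * _vonmises_bump(
            theta, math.radians(spec.cap_angle_deg), spec.cap_concentration
        )
    return prof


def simulate_ring_image(
    spec: RingSpec, image_size: int = 64, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a nuclear-envelope ring into a 2D image.

    The ring has a Gaussian radial cross-section (FWHM ``ring_width_px``)
    centred on ``radius_px`` around the image centre, modulated by the
    angular profile of :func:`ring_profile_truth`.  Patch angles are drawn
    uniformly from the seed.  Gaussian pixel noise of sd ``noise_sd`` is
    added.

    Returns ``(image, truth_profile, patch_angles_deg)`` where
    ``truth_profile`` is the angular intensity on a 1-degree grid.
    """
    sigma_r = spec.ring_width_px / 2.355  # FWHM -> sd
    if spec.radius_px + spec.ring_width_px / 2 + 3 * sigma_r > image_size / 2:
        raise ValueError("ring does not fit in the image")
    rng = np.random.default_rng(seed)
    patch_angles = rng.uniform(0.0, 360.0, size=spec.n_patches)
    truth = ring_profile_truth(spec, patch_angles)

    c = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    dx = xx - c
    dy = yy - c
    rho = np.hypot(dx, dy)
    # y grows downward in image coordinates; negate for CCW-from-+x angles
    theta = np.rad2deg(np.arctan2(-dy, dx)) % 360.0

    angular = np.full_like(rho, float(spec.base_intensity))
    for a in patch_angles:
        angular += spec.patch_amplitude * _vonmises_bump(
            np.deg2rad(theta), math.radians(a), spec.patch_concentration
        )
    if spec.cap_amplitude > 0:
        angular += spec.cap_amplitude * _vonmises_bump(
            np.deg2rad(theta), math.radians(spec.cap_angle_deg), spec.cap_concentration
        )
    radial = np.exp(-0.5 * ((rho - spec.radius_px) / sigma_r) ** 2)
    image = angular * radial
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return image, truth, patch_angles


def ring_integral_truth(spec: RingSpec, truth_profile: np.ndarray) -> float:
    """Analytic total image intensity implied by the ground-truth profile.

    Integrating the Gaussian radial cross-section against the area element
    ``rho drho dtheta`` gives ``radius * sqrt(2 pi) * sigma_r *
    integral(A(theta) dtheta)``.
    """
    sigma_r = spec.ring_width_px / 2.355
    return float(
        spec.radius_px * math.sqrt(2 * math.pi) * sigma_r
        * np.sum(truth_profile) * (2 * math.pi / truth_profile.size)
    )


# ---------------------------------------------------------------------------
# collapse series
# ---------------------------------------------------------------------------

def simulate_collapse_series(spec: CollapseSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate NE and SC size trajectories through a nuclear collapse.

    Columns: ``frame``, ``time_s``, ``ne_size_um``, ``sc_size_um``.  The NE
    shrinks at ``rate_pre`` per frame before contact and ``rate_post``
    after; the SC holds its size until contact and then shrinks.  Sizes
    driven negative are clipped at 0 with a warning.  The noise-free NE
    stays at or above the SC before contact; parameters violating that
    raise.
    """
    rng = np.random.default_rng(seed)
    frames = np.arange(spec.n_frames)
    cf = spec.contact_frame
    ne = np.where(
        frames <= cf,
        spec.ne_size0_um + spec.rate_pre * frames,
        spec.ne_size0_um + spec.rate_pre * cf + spec.rate_post * (frames - cf),
    ).astype(float)
    sc = np.where(
        frames <= cf,
        spec.sc_size0_um,
        spec.sc_size0_um + spec.sc_rate_post * (frames - cf),
    ).astype(float)
    if np.any(ne[: cf] < sc[: cf]):
        raise ValueError("NE size falls below SC size before the contact frame")
    if np.any(ne < 0) or np.any(sc < 0):
        warnings.warn("size trajectory clipped at 0", stacklevel=2)
        ne = np.clip(ne, 0.0, None)
        sc = np.clip(sc, 0.0, None)
    if spec.noise_sd > 0:
        ne = ne + rng.normal(0.0, spec.noise_sd, size=ne.size)
        sc = sc + rng.normal(0.0, spec.noise_sd, size=sc.size)
    return pd.DataFrame(
        {
            "frame": frames,
            "time_s": frames * spec.frame_interval_s,
            "ne_size_um": ne,
            "sc_size_um": sc,
        }
    )


# ---------------------------------------------------------------------------
# gonad layouts
# ---------------------------------------------------------------------------

def simulate_gonad_layout(spec: LayoutSpec, seed: int = 0) -> pd.DataFrame:
    """Populate a gonad axis with nuclei and per-zone status flags.

    Nuclei are uniform along the axis and split evenly across animals.
    The collapsed flag is Bernoulli with the nucleus's zone probability;
    if pairing/synapsis probabilities are given, ``him8_foci`` (1 =
    paired, 2 = unpaired) and ``coloc_fraction`` columns are added.
    """
    rng = np.random.default_rng(seed)
    n_zones = len(spec.zone_collapse_probs)
    pos = rng.uniform(0.0, spec.gonad_length, size=spec.n_nuclei)
    zone = np.minimum(
        (pos / spec.gonad_length * n_zones).astype(int), n_zones - 1
    )  # half-open bins, closed top
    probs = np.asarray(spec.zone_collapse_probs)[zone]
    collapsed = rng.random(spec.n_nuclei) < probs
    stage_idx = np.searchsorted(np.asarray(spec.stage_boundaries), pos, side="right")
    animal = rng.integers(0, spec.n_animals, size=spec.n_nuclei)
    out = pd.DataFrame(
        {
            "nucleus_id": np.arange(spec.n_nuclei),
            "animal_id": animal,
            "position": pos,
            "zone": zone + 1,  # 1-based, distal -> proximal
            "stage": np.asarray(spec.stage_labels)[stage_idx],
            "collapsed": collapsed,
        }
    )
    if spec.zone_pairing_probs is not None:
        if len(spec.zone_pairing_probs) != n_zones:
            raise ValueError("zone_pairing_probs length must match zone count")
        paired = rng.random(spec.n_nuclei) < np.asarray(spec.zone_pairing_probs)[zone]
        out["him8_foci"] = np.where(paired, 1, 2)
    if spec.zone_synapsis_probs is not None:
        if len(spec.zone_synapsis_probs) != n_zones:
            raise ValueError("zone_synapsis_probs length must match zone count")
        synapsed = rng.random(spec.n_nuclei) < np.asarray(spec.zone_synapsis_probs)[zone]
        out["coloc_fraction"] = np.where(
            synapsed, 1.0, rng.uniform(0.0, 0.8, size=spec.n_nuclei)
        )
    return out


# ---------------------------------------------------------------------------
# detection tables for tracking
# ---------------------------------------------------------------------------

def simulate_tracks(
    n_particles: int,
    motion: dict | None = None,
    drift_um_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_frames: int = 10,
    frame_interval_s: float = 5.0,
    box_um: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate 3D particle detections with optional common stage drift.

    ``motion`` is ``{"model": "stationary"|"directed"|"random-walk",
    "speed_um_per_frame": float}``.  Directed particles move along a random
    fixed direction; random walkers take isotropic Gaussian steps with
    per-axis sd equal to the speed parameter.  ``frame_interval_s``
    defaults to the 5-s cadence of the LINC-mobility time lapse.

    Returns ``(detections, truth)``: detections carry no identities
    (columns frame, t_s, x_um, y_um, z_um, shuffled within frame); truth
    adds the ``particle`` column.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    motion = {"model": "stationary", "speed_um_per_frame": 0.0, **(motion or {})}
    model = motion["model"]
    speed = float(motion["speed_um_per_frame"])
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box_um, size=(n_particles, 3))
    drift = np.asarray(drift_um_per_frame, dtype=float)

    if model == "directed":
        dirs = rng.normal(size=(n_particles, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    truth_rows = []
    for f in range(n_frames):
        if f > 0:
            if model == "directed":
                pos = pos + speed * dirs
            elif model == "random-walk":
                pos = pos + rng.normal(0.0, speed, size=pos.shape)
            elif model != "stationary":
                raise ValueError(f"unknown motion model {model!r}")
        observed = pos + f * drift
        for p in range(n_particles):
            truth_rows.append(
                {
                    "frame": f,
                    "t_s": f * frame_interval_s,
                    "particle": p,
                    "x_um": observed[p, 0],
                    "y_um": observed[p, 1],
                    "z_um": observed[p, 2],
                }
            )
    truth = pd.DataFrame(truth_rows)
    detections = (
        truth.sample(frac=1.0, random_state=int(rng.integers(2**31)))
        .sort_values("frame", kind="stable")
        .drop(columns="particle")
        .reset_index(drop=True)
    )
    return detections, truth
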
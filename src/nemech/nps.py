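"""Mechano-node-pore-sensing (mechano-NPS) current-pulse analysis.

A nucleus transiting a segmented microfluidic channel produces a current
pulse with two sub-pulses: a shallow one in the wide "sizing" segment and a
deeper one in the narrow "contraction" segment, separated by a brief
recovery while the particle crosses the node.  From each event we extract

* ``dI_s`` -- the sizing-segment current drop, which determines the nuclear
  diameter ``d_n`` through the resistive-pulse sizing relation,
* ``t_s``, ``t_c`` -- the transit times through the sizing and contraction
  segments; stiffer nuclei traverse the contraction more slowly,

and derive the applied strain ``eps = (d_n - w_c)/d_n`` and the whole-cell
deformability index (wCDI), a dimensionless, size-normalised quantity
inversely related to the Young's modulus.  Nuclei no wider than the
contraction channel (``d_n <= w_c``) experience zero strain and are
excluded from wCDI statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import median_abs_deviation

__all__ = [
    "ChannelGeometry",
    "CurrentTrace",
    "PulseEvent",
    "NucleusMeasurement",
    "DEFAULT_GEOMETRY",
    "relative_blockade",
    "preprocess_trace",
    "detect_events",
    "size_from_pulse",
    "applied_strain",
    "calibrate_with_beads",
    "compute_wcdi",
    "wcdi_default",
    "analyze_run",
    "CalibrationWarning",
]


class CalibrationWarning(UserWarning):
    """Raised when bead calibration data look too dispersed to trust."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Device dimensions and drive settings of the mechano-NPS channel.

    Lengths and widths in micrometres.  The default instance carries the
    dimensions of the single-node device used for nuclear measurements:
    a 9.9 um-high channel with a 700.4 x 5.9 um sizing segment, an
    80.4 x 50.4 um node and a 700.4 x 2.9 um contraction segment, driven
    at 6 V DC under 7 kPa.
    """

    height_um: float = 9.9
    sizing_length_um: float = 700.4
    sizing_width_um: float = 5.9
    node_length_um: float = 80.4
    node_width_um: float = 50.4
    contraction_length_um: float = 700.4
    contraction_width_um: float = 2.9
    voltage_v: float = 6.0
    pressure_kpa: float = 7.0

    def __post_init__(self) -> None:
        dims = (
            self.height_um,
            self.sizing_length_um,
            self.sizing_width_um,
            self.node_length_um,
            self.node_width_um,
            self.contraction_length_um,
            self.contraction_width_um,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all channel dimensions must be positive")
        if self.contraction_width_um >= self.sizing_width_um:
            raise ValueError("contraction segment must be narrower than sizing segment")

    def effective_diameter_um(self, segment: str = "sizing") -> float:
        """Effective diameter D_e = sqrt(4*w*h/pi) of a rectangular segment."""
        width = {
            "sizing": self.sizing_width_um,
            "contraction": self.contraction_width_um,
            "node": self.node_width_um,
        }[segment]
        return math.sqrt(4.0 * width * self.height_um / math.pi)


DEFAULT_GEOMETRY = ChannelGeometry()


@dataclass
class CurrentTrace:
    """A uniformly sampled current record.

    Attributes
    ----------
    time_s : ndarray
        Strictly increasing sample times in seconds.
    current_na : ndarray
        Measured current in nanoamperes.
    sampling_rate_hz : float
        Sample rate of the (possibly downsampled) record.
    baseline_na : float or None
        Estimated open-channel baseline; ``None`` until estimated.
    """

    time_s: np.ndarray
    current_na: np.ndarray
    sampling_rate_hz: float
    baseline_na: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_na = np.asarray(self.current_na, dtype=float)
        if self.time_s.shape != self.current_na.shape:
            raise ValueError("time and current must have equal length")
        if self.time_s.size > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.time_s)) and np.all(np.isfinite(self.current_na))):
            raise ValueError("trace contains non-finite values")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class PulseEvent:
    """One detected transit: sizing and contraction sub-pulse windows.

    Index windows are half-open ``[start, stop)`` into the trace the event
    was detected on and are ordered sizing -> node -> contraction.
    """

    sizing_window: tuple[int, int]
    contraction_window: tuple[int, int]
    dI_s_na: float
    dI_c_na: float
    t_s_s: float
    t_c_s: float

    def __post_init__(self) -> None:
        if self.t_s_s <= 0 or self.t_c_s <= 0:
            raise ValueError("transit times must be positive")
        if self.dI_s_na <= 0:
            raise ValueError("sizing sub-pulse depth must be positive")
        if not self.sizing_window[1] <= self.contraction_window[0]:
            raise ValueError("sub-pulse windows must be ordered sizing -> contraction")


@dataclass
class NucleusMeasurement:
    """Per-nucleus results: diameter, applied strain, wCDI and QC flag."""

    d_n_um: float
    strain: float
    wcdi: float | None
    included: bool
    event: PulseEvent | None = None


# ---------------------------------------------------------------------------
# sizing relation
# ---------------------------------------------------------------------------

def relative_blockade(
    diameter_um: float | np.ndarray,
    geometry: ChannelGeometry,
    segment: str = "sizing",
    calibration_constant: float = 1.0,
) -> float | np.ndarray:
    """Forward resistive-pulse sizing relation dI/I for a sphere.

    Uses the canonical node-pore relation ``dI/I = d^3 / (D_e^2 * L)`` with
    the large-particle correction ``1 / (1 - 0.8 (d/D_e)^3)``, where ``D_e``
    is the effective diameter of the (rectangular) segment.  The
    multiplicative ``calibration_constant`` absorbs device-to-device scale
    and is fit from bead data by :func:`calibrate_with_beads`.
    """
    d = np.asarray(diameter_um, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    de = geometry.effective_diameter_um(segment)
    length = (
        geometry.sizing_length_um if segment == "sizing" else geometry.contraction_length_um
    )
    ratio_cubed = (d / de) ** 3
    if np.any(0.8 * ratio_cubed >= 0.95):
        raise ValueError(
            f"particle too large for the {segment} segment sizing relation "
            f"(d={np.max(d):.3g} um vs D_e={de:.3g} um)"
        )
    rel = calibration_constant * d**3 / (de**2 * length) / (1.0 - 0.8 * ratio_cubed)
    return float(rel) if np.isscalar(diameter_um) else rel


def size_from_pulse(
    dI_s_na: float,
    baseline_na: float,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    calibration_constant: float = 1.0,
) -> float:
    """Invert the sizing relation: current drop -> particle diameter (um).

    Solved by bracketed root finding on the strictly monotone forward
    relation; absolute tolerance 1e-9 um.
    """
    if dI_s_na <= 0:
        raise ValueError("dI_s must be positive")
    if baseline_na <= 0:
        raise ValueError("baseline current must be positive")
    target = dI_s_na / baseline_na
    de = geometry.effective_diameter_um("sizing")
    # largest diameter for which the corrected relation stays finite
    d_hi = de * (0.95 / 0.8) ** (1.0 / 3.0) * (1.0 - 1e-9)
    hi_val = relative_blockade(d_hi, geometry, "sizing", calibration_constant)
    if target >= hi_val:
        raise ValueError(
            f"relative blockade {target:.3g} exceeds the invertible range "
            f"(max {hi_val:.3g}); no real diameter under the correction factor"
        )

    def f(d: float) -> float:
        return relative_blockade(d, geometry, "sizing", calibration_constant) - target

    return float(brentq(f, 1e-6, d_hi, xtol=1e-9))


def applied_strain(d_n_um: float, geometry: ChannelGeometry = DEFAULT_GEOMETRY) -> float:
    """Applied strain eps = (d_n - w_c)/d_n; zero when the nucleus fits the channel."""
    if d_n_um <= 0:
        raise ValueError("diameter must be positive")
    w_c = geometry.contraction_width_um
    return (d_n_um - w_c) / d_n_um if d_n_um > w_c else 0.0


def calibrate_with_beads(
    bead_dI_s_na: Sequence[float],
    baseline_na: float,
    true_diameter_um: float,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
) -> float:
    """Fit the sizing calibration constant from monodisperse bead pulses.

    Finds the constant for which the mean recovered diameter equals the
    beads' nominal diameter (least-squares in the single-constant case).
    Warns if the bead pulse depths are more dispersed than 20% of their
    mean, which usually indicates aggregates or debris.
    """
    depths = np.asarray(bead_dI_s_na, dtype=float)
    if depths.size < 5:
        raise ValueError("bead calibration requires at least 5 events")
    if np.std(depths, ddof=1) > 0.2 * np.mean(depths):
        warnings.warn(
            "bead dI_s dispersion exceeds 20% of the mean; calibration may be unreliable",
            CalibrationWarning,
            stacklevel=2,
        )

    def mean_recovered(const: float) -> float:
        return float(
            np.mean([size_from_pulse(d, baseline_na, geometry, const) for d in depths])
        )

    def f(log_c: float) -> float:
        return mean_recovered(math.exp(log_c)) - true_diameter_um

    return float(math.exp(brentq(f, -6.0, 6.0, xtol=1e-10)))


# ---------------------------------------------------------------------------
# wCDI
# ---------------------------------------------------------------------------

def wcdi_default(
    d_n_um: float, t_c_s: float, t_s_s: float, geometry: ChannelGeometry
) -> float:
    """Default whole-cell deformability index.

    ``wCDI = (L_c * h * t_s) / (d_n^2 * t_c)`` -- a dimensionless,
    size-normalised inverse contraction transit time.  Softer particles
    clear the contraction faster (smaller ``t_c``), so wCDI increases with
    deformability and is inversely related to the Young's modulus.
    """
    return (
        geometry.contraction_length_um
        * geometry.height_um
        * t_s_s
        / (d_n_um**2 * t_c_s)
    )


def compute_wcdi(
    d_n_um: float,
    t_c_s: float,
    t_s_s: float,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    formula: Callable[[float, float, float, ChannelGeometry], float] | None = None,
) -> float:
    """Whole-cell deformability index for one nucleus.

    The exact functional form is a pluggable strategy (``formula``); any
    admissible form is strictly decreasing in ``t_c`` at fixed size, so
    downstream comparisons bind only to that ordering.  Nuclei with
    ``d_n <= w_c`` experience zero strain and must be excluded upstream;
    calling this on such a nucleus raises.
    """
    if t_c_s <= 0 or t_s_s <= 0:
        raise ValueError("transit times must be positive")
    if d_n_um <= geometry.contraction_width_um:
        raise ValueError(
            "nucleus not wider than the contraction channel (strain 0); "
            "excluded from wCDI measurements"
        )
    fn = formula if formula is not None else wcdi_default
    return float(fn(d_n_um, t_c_s, t_s_s, geometry))


# ---------------------------------------------------------------------------
# trace processing
# ---------------------------------------------------------------------------

def _estimate_baseline(current: np.ndarray) -> float:
    # two-pass: pulses only ever drop the current, so samples above the
    # mid-range are mostly open-channel; a second pass restricted to the
    # noise cloud around that first estimate removes the residual bias
    # from shallow pulse samples caught in the band
    mid = 0.5 * (np.max(current) + np.min(current))
    upper = current[current >= mid]
    if upper.size == 0:
        return float(np.median(current))
    b0 = float(np.median(upper))
    above = current[current >= b0] - b0
    spread = (float(np.median(above)) / 0.6745 if above.size else 0.0) or 1e-12
    cloud = current[current >= b0 - 2.0 * spread]
    return float(np.median(cloud)) if cloud.size else b0


def _noise_sd(current: np.ndarray) -> float:
    # pulses only deflect the current downward, so deviations above the
    # baseline are pure noise; the median positive deviation of a Gaussian
    # is 0.6745 sigma.  A whole-trace (or band) MAD would be inflated by
    # the pulses themselves when they occupy much of the record.
    baseline = _estimate_baseline(current)
    above = current[current >= baseline] - baseline
    if above.size < 2:
        return float(median_abs_deviation(current, scale="normal")) or 1e-12
    sd = float(np.median(above)) / 0.6745
    if sd == 0.0:
        sd = float(np.std(current)) or 1e-12
    return sd


def preprocess_trace(
    trace: CurrentTrace, window_samples: int = 1, downsample_factor: int = 1
) -> CurrentTrace:
    """Rectangular (boxcar) smoothing followed by decimation.

    The moving average uses a centred window with reflected edges; the
    decimated record keeps every ``downsample_factor``-th sample starting
    at index 0.  The baseline is re-estimated on the result.
    """
    if window_samples < 1 or downsample_factor < 1:
        raise ValueError("window and factor must be >= 1")
    if window_samples > len(trace):
        raise ValueError("smoothing window longer than trace")
    current = trace.current_na
    if window_samples > 1:
        kernel = np.full(window_samples, 1.0 / window_samples)
        padded = np.pad(current, window_samples, mode="reflect")
        current = np.convolve(padded, kernel, mode="same")[
            window_samples : window_samples + current.size
        ]
    time = trace.time_s[::downsample_factor]
    current = current[::downsample_factor]
    out = CurrentTrace(
        time_s=time,
        current_na=current,
        sampling_rate_hz=trace.sampling_rate_hz / downsample_factor,
    )
    out.baseline_na = _estimate_baseline(out.current_na)
    return out


def _runs_below(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``mask`` is True."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2].tolist(), idx[1::2].tolist()))


def _plateau_depth(current: np.ndarray, baseline: float, window: tuple[int, int]) -> float:
    """Baseline minus the mean over the central 50% of the window."""
    start, stop = window
    n = stop - start
    lo = start + n // 4
    hi = stop - n // 4
    if hi <= lo:
        lo, hi = start, stop
    return baseline - float(np.mean(current[lo:hi]))


def detect_events(
    trace: CurrentTrace,
    threshold_k: float = 5.0,
    max_node_gap_factor: float = 0.5,
    min_run_samples: int = 10,
) -> list[PulseEvent]:
    """Detect transits and segment them into sizing/contraction sub-pulses.

    Samples below ``baseline - threshold_k * noise_sd`` form runs (the
    noise sd comes from the positive-side deviations, which the downward
    pulses cannot contaminate); nearby runs are clustered into one transit
    using ``max_node_gap_factor``.  Within each transit the sizing and
    contraction windows are the first and last regions whose blockade
    depth exceeds half the sizing-plateau depth -- the node's wide
    cross-section recovers the current nearly to baseline, so this split
    is insensitive to whether the shallow node blockade itself crossed
    the detection threshold.  ``dI_s`` is the baseline minus the mean of
    the sizing plateau (central 50% of samples, for noise robustness).
    Truncated events and events with a single sub-pulse are dropped with
    a warning.
    """
    if trace.baseline_na is None:
        raise ValueError("baseline not estimated; run preprocess_trace first")
    current = trace.current_na
    baseline = trace.baseline_na
    sd = _noise_sd(current)
    mask = current < baseline - threshold_k * sd
    raw_runs = _runs_below(mask)
    # merge runs separated by short gaps: noise flickers at the threshold
    # (e.g. a node blockade sitting right at it), or a fast node crossing.
    # Merging across a genuine node is harmless -- the depth-profile split
    # below recovers the two sub-pulses -- while inter-event gaps are
    # orders of magnitude longer than 5 * min_run_samples.
    merge_gap = 5 * min_run_samples
    merged: list[tuple[int, int]] = []
    for r in raw_runs:
        if merged and r[0] - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], r[1])
        else:
            merged.append(r)
    # runs still shorter than min_run_samples are noise excursions
    runs = [r for r in merged if r[1] - r[0] >= min_run_samples]
    dt = 1.0 / trace.sampling_rate_hz

    # cluster runs into transits: consecutive runs separated by less than
    # max_node_gap_factor times the longer neighbouring run belong to the
    # same event (the node recovery is much shorter than either sub-pulse,
    # while inter-event gaps are at least an event duration long)
    clusters: list[list[tuple[int, int]]] = []
    for r in runs:
        if clusters:
            prev = clusters[-1][-1]
            longest = max(b - a for a, b in clusters[-1])
            limit = max_node_gap_factor * max(longest, r[1] - r[0])
            if r[0] - prev[1] <= limit:
                clusters[-1].append(r)
                continue
        clusters.append([r])

    events: list[PulseEvent] = []
    n_dropped = 0
    for cluster in clusters:
        span = (cluster[0][0], cluster[-1][1])
        if span[0] == 0 or span[1] >= current.size:
            n_dropped += 1  # truncated at a trace edge
            continue
        # locate the two sub-pulses inside the span by thresholding the
        # depth profile at half the sizing-plateau depth: the node region
        # is far shallower than either plateau regardless of whether it
        # crossed the detection threshold
        depth = baseline - current[span[0] : span[1]]
        theta = 0.5 * np.percentile(depth, 25)
        sub = [
            (a + span[0], b + span[0])
            for a, b in _runs_below(depth > theta)
            if b - a >= min_run_samples
        ]
        if len(sub) < 2:
            n_dropped += 1  # single sub-pulse: no contraction passage
            continue
        sizing, contraction = sub[0], sub[-1]
        events.append(
            PulseEvent(
                sizing_window=sizing,
                contraction_window=contraction,
                dI_s_na=_plateau_depth(current, baseline, sizing),
                dI_c_na=_plateau_depth(current, baseline, contraction),
                t_s_s=(sizing[1] - sizing[0]) * dt,
                t_c_s=(contraction[1] - contraction[0]) * dt,
            )
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} incomplete pulse group(s) "
            "(single sub-pulse or truncated at trace edge)",
            stacklevel=2,
        )
    return events


def analyze_run(
    trace: CurrentTrace,
    geometry: ChannelGeometry = DEFAULT_GEOMETRY,
    *,
    window_samples: int = 5,
    downsample_factor: int = 1,
    threshold_k: float = 5.0,
    calibration_constant: float = 1.0,
    wcdi_formula: Callable | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full per-run analysis: preprocess -> detect -> size -> strain -> wCDI.

    Returns a per-event table and a summary dict with the included count,
    mean strain and mean wCDI.  Nuclei not wider than the contraction
    channel are flagged ``included=False`` and carry no wCDI.
    """
    if len(trace) == 0:
        empty = pd.DataFrame(
            columns=[
                "event_id", "dI_s_na", "t_s_s", "t_c_s",
                "d_n_um", "strain", "wcdi", "included",
            ]
        )
        return empty, {"n_events": 0, "n_included": 0, "mean_strain": np.nan, "mean_wcdi": np.nan}

    pre = preprocess_trace(trace, window_samples, downsample_factor)
    events = detect_events(pre, threshold_k)
    rows = []
    for k, ev in enumerate(events):
        d_n = size_from_pulse(ev.dI_s_na, pre.baseline_na, geometry, calibration_constant)
        eps = applied_strain(d_n, geometry)
        included = d_n > geometry.contraction_width_um
        wcdi = (
            compute_wcdi(d_n, ev.t_c_s, ev.t_s_s, geometry, wcdi_formula)
            if included
            else np.nan
        )
        rows.append(
            {
                "event_id": k,
                "dI_s_na": ev.dI_s_na,
                "t_s_s": ev.t_s_s,
                "t_c_s": ev.t_c_s,
                "d_n_um": d_n,
                "strain": eps,
                "wcdi": wcdi,
                "included": included,
            }
        )
    table = pd.DataFrame(rows)
    included = table[table["included"]] if len(table) else table
    summary = {
        "n_events": len(table),
        "n_included": int(included.shape[0]) if len(table) else 0,
        "mean_strain": float(included["strain"].mean()) if len(included) else np.nan,
        "mean_wcdi": float(included["wcdi"].mean()) if len(included) else np.nan,
    }
    return table, summary
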
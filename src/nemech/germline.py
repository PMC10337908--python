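"""Zone-based scoring along the germline (gonad) axis.

The distal-to-proximal gonad axis is partitioned into equal-length zones
(six for collapse scoring, five for pairing/synapsis) and per-zone
fractions of nuclei satisfying a predicate are computed, pooled and per
animal.  Pairing is scored from HIM-8 focus counts (one focus = paired
homologs), synapsis from the SYP-1/HTP-3 colocalization fraction, and
collapse from a status flag (ground truth in synthetic data, or a
volume-based predicate on real measurements).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .stats import bh_adjust

__all__ = [
    "ZoneSummary",
    "partition_zones",
    "score_pairing",
    "score_synapsis",
    "collapse_predicate_volume",
    "zone_fractions",
    "compare_zone_proportions",
]


@dataclass
class ZoneSummary:
    """Per-zone fractions of nuclei satisfying a predicate.

    ``table`` has one row per zone (1-based, distal -> proximal) with the
    pooled count ``n``, successes ``k``, pooled ``fraction`` (NaN for
    empty zones), and the across-animal mean and sample SD of per-animal
    fractions.  ``per_animal`` holds the underlying per-animal rows.
    """

    table: pd.DataFrame
    per_animal: pd.DataFrame
    predicate: str = ""


def partition_zones(
    positions: np.ndarray, gonad_length: float, n_zones: int
) -> np.ndarray:
    """Assign each axial position to one of ``n_zones`` equal-length zones.

    Zone i (1-based) covers [(i-1) L/n, i L/n); the last zone is closed at
    L so the zones partition [0, L] exactly.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    if gonad_length <= 0:
        raise ValueError("gonad_length must be positive")
    pos = np.asarray(positions, dtype=float)
    if np.any((pos < 0) | (pos > gonad_length)):
        raise ValueError("positions outside [0, gonad_length]")
    zone = np.floor(pos / gonad_length * n_zones).astype(int) + 1
    return np.minimum(zone, n_zones)  # position exactly L -> last zone


def score_pairing(focus_counts: Sequence[int], max_foci_paired: int = 1) -> np.ndarray:
    """Score X-chromosome pairing from HIM-8 focus counts.

    One focus means the homologs are paired; two means unpaired.  A count
    of zero passes the threshold but is flagged for review (it usually
    indicates a detection failure rather than pairing).
    """
    counts = np.asarray(focus_counts, dtype=int)
    if np.any(counts < 0):
        raise ValueError("focus counts must be >= 0")
    n_zero = int(np.sum(counts == 0))
    if n_zero:
        warnings.warn(
            f"{n_zero} nucleus/nuclei with 0 foci scored as paired; review recommended",
            stacklevel=2,
        )
    return counts <= max_foci_paired


def score_synapsis(coloc_fraction: Sequence[float], threshold: float = 0.95) -> np.ndarray:
    """Score complete synapsis: SYP-1/HTP-3 colocalization >= threshold."""
    frac = np.asarray(coloc_fraction, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("colocalization fractions must be in [0, 1]")
    return frac >= threshold


def collapse_predicate_volume(
    volumes: np.ndarray, zones: np.ndarray, factor: float = 0.5
) -> np.ndarray:
    """Volume-based collapse call for real measurements.

    A nucleus is called collapsed when its volume is below ``factor``
    times the median volume of its zone, mirroring the criterion of a
    smaller, hypercondensed nucleus relative to its neighbours.
    """
    volumes = np.asarray(volumes, dtype=float)
    zones = np.asarray(zones)
    out = np.zeros(volumes.size, dtype=bool)
    for z in np.unique(zones):
        sel = zones == z
        out[sel] = volumes[sel] < factor * np.median(volumes[sel])
    return out


def zone_fractions(
    layout: pd.DataFrame,
    predicate: str | Callable[[pd.DataFrame], np.ndarray],
    n_zones: int = 6,
    gonad_length: float | None = None,
) -> ZoneSummary:
    """Per-zone fractions of nuclei satisfying ``predicate``.

    ``layout`` needs columns ``position`` and ``animal_id``; ``predicate``
    is either the name of a boolean column or a callable on the layout.
    Empty zones are reported with NaN fractions, not 0.
    """
    if layout.empty:
        raise ValueError("layout is empty")
    if gonad_length is None:
        gonad_length = float(layout["position"].max())
    zones = partition_zones(layout["position"].to_numpy(), gonad_length, n_zones)
    flags = (
        layout[predicate].to_numpy(dtype=bool)
        if isinstance(predicate, str)
        else np.asarray(predicate(layout), dtype=bool)
    )
    df = pd.DataFrame(
        {"zone": zones, "animal_id": layout["animal_id"].to_numpy(), "flag": flags}
    )

    pooled = (
        df.groupby("zone")["flag"]
        .agg(n="size", k="sum")
        .reindex(range(1, n_zones + 1))
        .fillna({"n": 0, "k": 0})
        .astype({"n": int, "k": int})
        .reset_index()
    )
    pooled["fraction"] = np.where(pooled["n"] > 0, pooled["k"] / pooled["n"].replace(0, 1), np.nan)

    per_animal = (
        df.groupby(["zone", "animal_id"])["flag"].agg(n="size", k="sum").reset_index()
    )
    per_animal["fraction"] = per_animal["k"] / per_animal["n"]
    stats = (
        per_animal.groupby("zone")["fraction"]
        .agg(mean_across_animals="mean", sd_across_animals=lambda s: s.std(ddof=1))
        .reindex(range(1, n_zones + 1))
        .reset_index()
    )
    table = pooled.merge(stats, on="zone", how="left")
    name = predicate if isinstance(predicate, str) else getattr(predicate, "__name__", "custom")
    return ZoneSummary(table=table, per_animal=per_animal, predicate=name)


def compare_zone_proportions(a: ZoneSummary, b: ZoneSummary) -> pd.DataFrame:
    """Per-zone two-sample proportion comparison with BH adjustment.

    Each zone's 2x2 count table is tested with a chi-square test with
    continuity correction; zones with a zero row/column total or expected
    counts below 5 fall back to Fisher's exact test (logged in the
    ``method`` column).  P values are Benjamini-Hochberg adjusted across
    zones.
    """
    ta, tb = a.table.set_index("zone"), b.table.set_index("zone")
    zones = sorted(set(ta.index) & set(tb.index))
    rows = []
    for z in zones:
        ka, na = int(ta.loc[z, "k"]), int(ta.loc[z, "n"])
        kb, nb = int(tb.loc[z, "k"]), int(tb.loc[z, "n"])
        if na == 0 or nb == 0:
            rows.append({"zone": z, "p": np.nan, "method": "empty"})
            continue
        table = np.array([[ka, na - ka], [kb, nb - kb]])
        expected_ok = np.all(
            np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum() >= 5
        )
        if not expected_ok or np.any(table.sum(axis=0) == 0):
            _, p = fisher_exact(table)
            method = "fisher"
        else:
            _, p, _, _ = chi2_contingency(table, correction=True)
            method = "chi2-cc"
        rows.append({"zone": z, "p": float(p), "method": method})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if valid.any():
        adj[valid.to_numpy()] = bh_adjust(out.loc[valid, "p"].to_numpy())
    out["p_adj"] = adj
    return out
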
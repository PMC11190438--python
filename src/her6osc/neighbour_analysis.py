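"""Spatial heterogeneity between neighbouring nuclei in 3D snapshots.

Every nucleus is paired with its nearest neighbour by 3D Euclidean distance;
paired intensities are then summarised as correlations and ordered
high/low ratios.  Locally similar expression gives ratios near 1 and high
correlation; salt-and-pepper interspersion gives large ratios and reduced or
negative correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "NeighbourPairSet",
    "nearest_neighbour_pairs",
    "pair_intensity_ratio",
    "pair_correlation",
    "venus_positive_fraction",
    "persistent_close_pairs",
]


@dataclass
class NeighbourPairSet:
    pairs: pd.DataFrame     # id1, id2, distance_um, I1/I2 per channel


def nearest_neighbour_pairs(snapshot: pd.DataFrame,
                            channels: tuple[str, ...] = ("venus", "nuclear_marker")
                            ) -> NeighbourPairSet:
    """Pair each nucleus with its single nearest neighbour.

    Pairs are directional (cell 1 -> its neighbour), so a nucleus may appear
    as cell 2 in several pairs.  Ties from duplicate coordinates are broken
    by id order with a warning.
    """
    if len(snapshot) < 2:
        raise ValueError("need at least two nuclei")
    if snapshot["nucleus_id"].duplicated().any():
        raise ValueError("nucleus ids must be unique within a snapshot")
    snap = snapshot.reset_index(drop=True)
    xyz = snap[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValueError("coordinates must be finite")
    tree = cKDTree(xyz)
    dist, idx = tree.query(xyz, k=2)
    nn_dist, nn_idx = dist[:, 1], idx[:, 1]
    dup = nn_dist == 0
    if dup.any():
        logger.warning("%d duplicate coordinates; ties broken by id order",
                       int(dup.sum()))
    rows = {
        "id1": snap["nucleus_id"].to_numpy(),
        "id2": snap["nucleus_id"].to_numpy()[nn_idx],
        "distance_um": nn_dist,
    }
    for ch in channels:
        if ch in snap.columns:
            rows[f"I1_{ch}"] = snap[ch].to_numpy(dtype=float)
            rows[f"I2_{ch}"] = snap[ch].to_numpy(dtype=float)[nn_idx]
    return NeighbourPairSet(pairs=pd.DataFrame(rows))


def pair_intensity_ratio(pairs: NeighbourPairSet, channel: str = "venus",
                         ordered: bool = True) -> float:
    """Mean neighbour intensity ratio over all pairs.

    With the default ordered convention the ratio is max/min per pair, so
    the mean is >= 1 and equals 1 only when every pair is exactly matched.
    ``ordered=False`` gives the signed cell1/cell2 ratio instead.
    """
    df = pairs.pairs
    i1 = df[f"I1_{channel}"].to_numpy(dtype=float)
    i2 = df[f"I2_{channel}"].to_numpy(dtype=float)
    ok = (i1 > 0) & (i2 > 0)
    if not ok.all():
        logger.info("dropping %d pairs with zero intensity", int((~ok).sum()))
    i1, i2 = i1[ok], i2[ok]
    if i1.size == 0:
        raise ValueError("no valid pairs on this channel")
    if ordered:
        ratio = np.maximum(i1, i2) / np.minimum(i1, i2)
    else:
        ratio = i1 / i2
    return float(ratio.mean())


def pair_correlation(pairs: NeighbourPairSet, channel: str = "venus") -> float:
    """Pearson correlation between cell-1 and cell-2 intensities."""
    df = pairs.pairs
    if len(df) < 3:
        raise ValueError("need at least three pairs")
    i1 = df[f"I1_{channel}"].to_numpy(dtype=float)
    i2 = df[f"I2_{channel}"].to_numpy(dtype=float)
    if i1.std() == 0 or i2.std() == 0:
        return float("nan")
    return float(np.corrcoef(i1, i2)[0, 1])


def venus_positive_fraction(snapshot: pd.DataFrame, background,
                            mad_multiplier: float = 3.0,
                            channel: str = "venus") -> float:
    """Fraction of nuclei above a background-derived expression threshold.

    The threshold starts from the per-embryo background median and adds
    ``mad_multiplier`` background MADs (default 3, roughly two Gaussian
    standard deviations) — a deterministic stand-in for the manual
    threshold adjustment used on real embryos.
    """
    if len(snapshot) == 0:
        raise ValueError("empty snapshot")
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("empty background sample")
    med = np.median(bg)
    mad = np.median(np.abs(bg - med))
    threshold = med + mad_multiplier * mad
    return float((snapshot[channel].to_numpy(dtype=float) > threshold).mean())


def persistent_close_pairs(tracks: pd.DataFrame,
                           max_mean_distance: float = 15.0) -> pd.DataFrame:
    """Track pairs that stay close on average over their shared time points.

    For each track the minimal mean-3D-distance partner is found; pairs with
    mean distance below ``max_mean_distance`` (microns) are kept.  Candidate
    pairs without temporal overlap are skipped.
    """
    needed = {"cell_id", "time_h", "x", "y", "z"}
    if not needed.issubset(tracks.columns):
        raise ValueError(f"tracks need columns {sorted(needed)}")
    by_cell = {
        cid: g.sort_values("time_h").set_index("time_h")[["x", "y", "z"]]
        for cid, g in tracks.groupby("cell_id")
    }
    ids = sorted(by_cell)
    mean_dist: dict[tuple[str, str], float] = {}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            ga, gb = by_cell[ids[a]], by_cell[ids[b]]
            shared = ga.index.intersection(gb.index)
            if len(shared) == 0:
                continue
            d = np.linalg.norm(
                ga.loc[shared].to_numpy() - gb.loc[shared].to_numpy(), axis=1
            )
            mean_dist[(ids[a], ids[b])] = float(d.mean())
    rows = []
    for cid in ids:
        candidates = {
            other: d for (x, y), d in mean_dist.items()
            for other in ((y,) if x == cid else (x,) if y == cid else ())
        }
        if not candidates:
            continue
        partner = min(candidates, key=candidates.get)
        if candidates[partner] < max_mean_distance:
            rows.append({"cell_id": cid, "partner": partner,
                         "mean_distance_um": candidates[partner]})
    return pd.DataFrame(rows, columns=["cell_id", "partner", "mean_distance_um"])
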
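"""Axonal differentiation index and threshold analyses.

A neurite is stained for Tau-1 (axonal marker) and MAP2 (somatodendritic
marker) and the two channels are sampled along the neurite path.  The
axonal differentiation index compares the within-channel contrast:

    I_diff = [(I_Tau^max + 1) / (I_Tau^min + 1)]
           / [(I_MAP2^max + 1) / (I_MAP2^min + 1)]

where max/min are the peak and background intensities along the neurite
(a.u., nonnegative).  The +1 offset keeps the ratios finite when a channel
reaches zero.  A neurite is classified as an axon when I_diff exceeds a
threshold, 1.0 by convention; the tie at exactly 1.0 is resolved to
non-axon (axons are strictly above threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DEFAULT_THRESHOLD",
    "DEFAULT_SOMA_DIAMETER",
    "SWEEP_THRESHOLDS",
    "ThresholdSweepResult",
    "profile_extrema",
    "compute_idiff",
    "classify",
    "apply_exclusion",
    "add_idiff",
    "threshold_sweep",
    "extrema_from_images",
]

DEFAULT_THRESHOLD = 1.0
#: Soma diameter (μm) assumed when not measured; microchambers are 40 μm wide.
DEFAULT_SOMA_DIAMETER = 20.0
#: I_diff cutoffs of the threshold sensitivity sweep.
SWEEP_THRESHOLDS = (0.80, 0.90, 1.00, 1.10)


def profile_extrema(profile) -> tuple[float, float, float, float]:
    """Per-channel max/min of the intensities sampled along a neurite.

    ``profile`` is any object with ``tau_values`` and ``map2_values``
    array attributes (at least two samples each).  The minimum serves as
    the background term of the index.
    """
    tau = np.asarray(profile.tau_values, dtype=float)
    map2 = np.asarray(profile.map2_values, dtype=float)
    if tau.size < 2 or map2.size < 2:
        raise ValueError("profile must contain at least 2 samples per channel")
    return (
        float(tau.max()),
        float(tau.min()),
        float(map2.max()),
        float(map2.min()),
    )


def compute_idiff(
    tau_max: float, tau_min: float, map2_max: float, map2_min: float
) -> float:
    """Axonal differentiation index from channel extrema.

    All extrema must be nonnegative with max >= min per channel; the result
    is finite and strictly positive.  Swapping the Tau and MAP2 extrema maps
    the index to its reciprocal.
    """
    vals = (tau_max, tau_min, map2_max, map2_min)
    if any(v < 0 for v in vals):
        raise ValueError(f"intensities must be nonnegative, got {vals}")
    if tau_max < tau_min or map2_max < map2_min:
        raise ValueError(f"channel max < min: {vals}")
    return ((tau_max + 1.0) / (tau_min + 1.0)) / (
        (map2_max + 1.0) / (map2_min + 1.0)
    )


def classify(i_diff: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """Axon iff ``i_diff > threshold`` (strict; a tie is non-axon)."""
    if i_diff <= 0:
        raise ValueError(f"i_diff must be positive, got {i_diff}")
    return i_diff > threshold


def apply_exclusion(
    length_in_chamber: float, soma_diameter: float = DEFAULT_SOMA_DIAMETER
) -> bool:
    """Exclude a neuron whose in-chamber outgrowth escapes confinement.

    A sample is excluded when stray neurite extension inside the
    microchamber exceeds twice the soma diameter (strict); at exactly 2x
    the record is kept.  This screens confinement failures and is distinct
    from the guided neurite length in the microchannel.
    """
    if length_in_chamber <= 0 or soma_diameter <= 0:
        raise ValueError("lengths must be positive")
    return length_in_chamber > 2.0 * soma_diameter


def add_idiff(
    df: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Return a copy with ``i_diff`` and ``is_axon`` columns (re)computed
    from the extrema columns of the measurement table."""
    out = df.copy()
    num = (out["tau_max"].to_numpy(float) + 1.0) / (
        out["tau_min"].to_numpy(float) + 1.0
    )
    den = (out["map2_max"].to_numpy(float) + 1.0) / (
        out["map2_min"].to_numpy(float) + 1.0
    )
    out["i_diff"] = num / den
    out["is_axon"] = (out["i_diff"] > threshold).astype(int)
    return out


@dataclass
class ThresholdSweepResult:
    """Polarization rate per length bin at several I_diff thresholds.

    ``table`` has one row per (threshold, bin) with columns
    ``threshold, bin_left, bin_right, n, n_axon, rate`` — ``rate`` is NaN
    for empty bins.  ``monotone`` flags, per threshold, whether the rate is
    non-decreasing across non-empty bins.
    """

    thresholds: tuple[float, ...]
    bin_edges: np.ndarray
    table: pd.DataFrame
    monotone: dict[float, bool]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def threshold_sweep(
    df: pd.DataFrame,
    thresholds=SWEEP_THRESHOLDS,
    bin_width: float = 20.0,
) -> ThresholdSweepResult:
    """Histogram of polarization rate versus length at each threshold.

    Consumes non-excluded records with ``length_um`` and ``i_diff``; bins
    start at 0 μm.  Bin occupancies are identical across thresholds (the
    records are shared; only the axon calls change).
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    use = df
    if "excluded" in df.columns:
        use = df[~df["excluded"].astype(bool)]
    lengths = use["length_um"].to_numpy(float)
    idiff = use["i_diff"].to_numpy(float)
    if lengths.size == 0:
        raise ValueError("no non-excluded records to sweep")

    n_bins = int(np.ceil(lengths.max() / bin_width))
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    # right-open bins [left, right); the last bin is closed on the right
    which = np.clip(np.digitize(lengths, edges) - 1, 0, n_bins - 1)

    rows = []
    monotone: dict[float, bool] = {}
    for t in thresholds:
        axon = idiff > t
        rates = []
        for b in range(n_bins):
            in_bin = which == b
            n = int(in_bin.sum())
            n_axon = int(axon[in_bin].sum())
            rate = n_axon / n if n else float("nan")
            rows.append(
                {
                    "threshold": t,
                    "bin_left": edges[b],
                    "bin_right": edges[b + 1],
                    "n": n,
                    "n_axon": n_axon,
                    "rate": rate,
                }
            )
            if n:
                rates.append(rate)
        monotone[t] = bool(np.all(np.diff(rates) >= 0)) if rates else True
    return ThresholdSweepResult(
        thresholds=tuple(thresholds),
        bin_edges=edges,
        table=pd.DataFrame(rows),
        monotone=monotone,
    )


def extrema_from_images(
    tau_image,
    map2_image,
    path_xy,
    background: str = "off_path",
    off_path_distance_px: float = 3.0,
) -> tuple[float, float, float, float]:
    """Channel extrema sampled along a neurite path in a two-channel image.

    ``path_xy`` is an (n, 2) array of (x_px, y_px) pixel coordinates ordered
    from the soma.  With ``background="off_path"`` the median intensity of
    pixels farther than ``off_path_distance_px`` from the path is subtracted
    from each channel and negative values are clipped to 0, so the +1 offset
    of the index stays well defined; ``background="none"`` samples raw
    values.
    """
    tau_img = np.asarray(tau_image, dtype=float)
    map2_img = np.asarray(map2_image, dtype=float)
    xy = np.asarray(path_xy)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ValueError("path must be an (n>=2, 2) array of (x, y) pixels")
    xs = np.round(xy[:, 0]).astype(int)
    ys = np.round(xy[:, 1]).astype(int)
    if (
        xs.min() < 0
        or ys.min() < 0
        or xs.max() >= tau_img.shape[1]
        or ys.max() >= tau_img.shape[0]
    ):
        raise ValueError("path coordinates fall outside the image")

    if background == "off_path":
        on_path = np.zeros(tau_img.shape, dtype=bool)
        on_path[ys, xs] = True
        dist = ndimage.distance_transform_edt(~on_path)
        far = dist > off_path_distance_px
        if far.any():
            tau_img = np.clip(tau_img - np.median(tau_img[far]), 0.0, None)
            map2_img = np.clip(map2_img - np.median(map2_img[far]), 0.0, None)
    elif background != "none":
        raise ValueError(f"unknown background mode {background!r}")

    tau_vals = tau_img[ys, xs]
    map2_vals = map2_img[ys, xs]
    return (
        float(tau_vals.max()),
        float(tau_vals.min()),
        float(map2_vals.max()),
        float(map2_vals.min()),
    )
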
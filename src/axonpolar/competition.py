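"""Two-neurite competition analyses.

Operates on pair datasets in the measurement-table schema (two rows per
``pair_id``).  Provides pooled and conditional sigmoid fits, pair-outcome
classification (none / single / dual axon), stepwise-paradigm pattern
assignment, critical-length shifts with delta-method standard errors, and
the probability-colored outcome map (red = axon probability of the
longer/first neurite, blue = shorter/second, magenta = both).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FitError, SigmoidFit, fit_sigmoid, sigmoid_probability
from .quantify import DEFAULT_THRESHOLD

__all__ = [
    "PairOutcome",
    "StepwisePattern",
    "ProbabilityMap",
    "pair_table",
    "classify_pair_outcome",
    "pair_outcome_counts",
    "fit_pair_pooled",
    "fit_conditional",
    "lc_shift",
    "stepwise_pattern",
    "probability_map",
    "pair_bootstrap_se",
]

PAIR_OUTCOMES = ("none", "single", "dual")
STEPWISE_PATTERNS = ("none", "first_wins", "second_wins", "dual")


def pair_table(df: pd.DataFrame) -> pd.DataFrame:
    """Wide per-pair view of a two-row-per-pair measurement table.

    Rows within a pair are ordered by ``open_day`` then ``neurite_id`` so
    that, in the stepwise paradigm, suffix ``_1`` is the first-opened
    channel.  Columns: ``length_1/2, i_diff_1/2, is_axon_1/2, open_day_1/2,
    length_at_opening_um`` plus ``paradigm``.
    """
    if "pair_id" not in df.columns:
        raise ValueError("pair table requires a pair_id column")
    rows = []
    for pair_id, grp in df.groupby("pair_id", sort=True):
        if len(grp) != 2:
            raise ValueError(f"pair {pair_id!r} has {len(grp)} rows, expected 2")
        grp = grp.sort_values(["open_day", "neurite_id"])
        a, b = grp.iloc[0], grp.iloc[1]
        rows.append(
            {
                "pair_id": pair_id,
                "paradigm": a["paradigm"],
                "length_1": float(a["length_um"]),
                "length_2": float(b["length_um"]),
                "i_diff_1": float(a["i_diff"]),
                "i_diff_2": float(b["i_diff"]),
                "is_axon_1": int(a["is_axon"]),
                "is_axon_2": int(b["is_axon"]),
                "open_day_1": int(a["open_day"]),
                "open_day_2": int(b["open_day"]),
                "length_at_opening_um": float(a.get("length_at_opening_um", float("nan"))),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PairOutcome:
    pair_id: str
    outcome: str  # none | single | dual
    n_axons: int


def classify_pair_outcome(
    i_diff_1: float, i_diff_2: float, threshold: float = DEFAULT_THRESHOLD
) -> str:
    """Pair outcome from the two indices: 0, 1 or 2 neurites above threshold."""
    for v in (i_diff_1, i_diff_2):
        if v is None or not np.isfinite(v):
            raise ValueError("both neurites must carry a finite i_diff")
    n_axons = int(i_diff_1 > threshold) + int(i_diff_2 > threshold)
    return PAIR_OUTCOMES[n_axons]


def pair_outcome_counts(
    df: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> dict[str, int]:
    """Outcome tally over all pairs; counts sum to the number of pairs."""
    wide = pair_table(df)
    counts = {k: 0 for k in PAIR_OUTCOMES}
    for _, row in wide.iterrows():
        counts[classify_pair_outcome(row["i_diff_1"], row["i_diff_2"], threshold)] += 1
    return counts


def _pooled_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    use = df
    if "excluded" in df.columns:
        use = df[~df["excluded"].astype(bool)]
    return use["length_um"].to_numpy(float), use["is_axon"].to_numpy(float)


def fit_pair_pooled(df: pd.DataFrame, **fit_kwargs) -> SigmoidFit:
    """Sigmoid fit pooling every neurite of every pair as independent.

    Treating paired neurites as independent observations matches plotting
    each neurite as its own point on the length-probability axis; use
    :func:`pair_bootstrap_se` for standard errors that respect within-pair
    correlation.
    """
    n_pairs = df["pair_id"].nunique()
    if n_pairs < 2:
        raise FitError(f"need at least 2 pairs, got {n_pairs}")
    lengths, labels = _pooled_arrays(df)
    return fit_sigmoid(lengths, labels, **fit_kwargs)


def fit_conditional(df: pd.DataFrame, Lt_ref: float, **fit_kwargs) -> SigmoidFit:
    """Sigmoid fit restricted to neurites whose partner exceeds ``Lt_ref``.

    ``Lt_ref`` should be the definitive length of a reference
    (single-neurite) fit.  The conditioning partner itself enters the
    subset only if its own partner also exceeds ``Lt_ref``.
    """
    wide = pair_table(df)
    lengths, labels = [], []
    for _, row in wide.iterrows():
        if row["length_2"] > Lt_ref:
            lengths.append(row["length_1"])
            labels.append(row["is_axon_1"])
        if row["length_1"] > Lt_ref:
            lengths.append(row["length_2"])
            labels.append(row["is_axon_2"])
    if not lengths:
        raise FitError(
            f"no neurite has a partner longer than Lt_ref={Lt_ref:g} μm"
        )
    try:
        fit = fit_sigmoid(np.asarray(lengths), np.asarray(labels), **fit_kwargs)
    except FitError as err:
        raise FitError(
            f"conditional subset (partner length > {Lt_ref:g} μm, "
            f"n={len(lengths)}): {err}"
        ) from err
    return fit


def lc_shift(fit_a: SigmoidFit, fit_b: SigmoidFit) -> tuple[float, float]:
    """Critical-length shift ``fit_b.Lc - fit_a.Lc`` with delta-method SE.

    The two fits are treated as independent, so the variance of the
    difference is the sum of the two Lc variances.
    """
    if not (fit_a.converged and fit_b.converged):
        raise FitError("both fits must be converged")
    delta = fit_b.Lc - fit_a.Lc
    var = float(fit_a.covariance[0, 0]) + float(fit_b.covariance[0, 0])
    se = math.sqrt(var) if np.isfinite(var) and var >= 0 else float("nan")
    return delta, se


@dataclass(frozen=True)
class StepwisePattern:
    """Axonal-fate pattern of one stepwise pair.

    ``pattern``: which neurite(s) became the axon — ``first_wins``,
    ``second_wins``, ``dual``, or ``none`` (possible in principle, though
    a cohort may not contain it).  ``longest_is_axon`` records whether the
    finally-longest neurite carries an axon label.
    """

    pattern: str
    longest_is_axon: bool


def stepwise_pattern(
    length_1: float,
    length_2: float,
    is_axon_1: bool | int,
    is_axon_2: bool | int,
) -> StepwisePattern:
    """Assign the stepwise-paradigm fate pattern from final lengths and flags.

    Suffix 1 is the first-opened channel, suffix 2 the later one.
    """
    a1, a2 = bool(is_axon_1), bool(is_axon_2)
    if a1 and a2:
        pattern = "dual"
    elif a1:
        pattern = "first_wins"
    elif a2:
        pattern = "second_wins"
    else:
        pattern = "none"
    longer_is_1 = length_1 >= length_2
    longest_is_axon = (a1 if longer_is_1 else a2) if (a1 or a2) else False
    return StepwisePattern(pattern=pattern, longest_is_axon=longest_is_axon)


def stepwise_patterns(df: pd.DataFrame) -> pd.DataFrame:
    """Per-pair pattern table for a stepwise dataset."""
    wide = pair_table(df)
    recs = []
    for _, row in wide.iterrows():
        pat = stepwise_pattern(
            row["length_1"], row["length_2"], row["is_axon_1"], row["is_axon_2"]
        )
        recs.append(
            {
                "pair_id": row["pair_id"],
                "pattern": pat.pattern,
                "longest_is_axon": pat.longest_is_axon,
            }
        )
    return pd.DataFrame(recs)


@dataclass
class ProbabilityMap:
    """Axon-specification probabilities over a pair-length plane.

    ``p_x[i]`` depends only on ``x_grid[i]`` and ``p_y[j]`` only on
    ``y_grid[j]`` (separable by construction): x is the longer (or first)
    neurite, y the shorter (or second).
    """

    x_grid: np.ndarray
    y_grid: np.ndarray
    p_x: np.ndarray
    p_y: np.ndarray

    def grid(self) -> pd.DataFrame:
        """Long-form cell table (x_um, y_um, p_x, p_y)."""
        xx, yy = np.meshgrid(self.x_grid, self.y_grid, indexing="ij")
        px, py = np.meshgrid(self.p_x, self.p_y, indexing="ij")
        return pd.DataFrame(
            {
                "x_um": xx.ravel(),
                "y_um": yy.ravel(),
                "p_x": px.ravel(),
                "p_y": py.ravel(),
            }
        )

    def to_rgb(self) -> np.ndarray:
        """8-bit RGB rendering: red = p_x, blue = p_y (magenta = both).

        Rows run from large y at the top to small y at the bottom, image
        convention.
        """
        px, py = np.meshgrid(self.p_x, self.p_y, indexing="ij")
        rgb = np.zeros(px.shape + (3,), dtype=np.uint8)
        rgb[..., 0] = np.round(255 * px).astype(np.uint8)
        rgb[..., 2] = np.round(255 * py).astype(np.uint8)
        return np.transpose(rgb, (1, 0, 2))[::-1]

    def save_png(self, path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, self.to_rgb())


def probability_map(fit: SigmoidFit, x_grid, y_grid) -> ProbabilityMap:
    """Evaluate a reference fit over a grid of pair lengths."""
    if not fit.converged:
        raise FitError("probability map requires a converged fit")
    x = np.asarray(x_grid, dtype=float)
    y = np.asarray(y_grid, dtype=float)
    return ProbabilityMap(
        x_grid=x,
        y_grid=y,
        p_x=sigmoid_probability(x, fit.Lc, fit.sigma),
        p_y=sigmoid_probability(y, fit.Lc, fit.sigma),
    )


def pair_bootstrap_se(
    df: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
    **fit_kwargs,
) -> dict[str, float]:
    """Pair-resampling bootstrap SEs for the pooled fit's (Lc, sigma).

    Resamples whole pairs with replacement, refits, and returns the
    standard deviations over successful replicates; respects within-pair
    correlation that the pooled fit ignores.
    """
    rng = np.random.default_rng(seed)
    pair_ids = df["pair_id"].unique()
    groups = {pid: df[df["pair_id"] == pid] for pid in pair_ids}
    lcs, sigmas = [], []
    for _ in range(n_boot):
        take = rng.choice(pair_ids, size=pair_ids.size, replace=True)
        boot = pd.concat([groups[pid] for pid in take], ignore_index=True)
        lengths, labels = _pooled_arrays(boot)
        if np.ptp(labels) == 0:
            continue
        try:
            fit = fit_sigmoid(lengths, labels, **fit_kwargs)
        except FitError:
            continue
        lcs.append(fit.Lc)
        sigmas.append(fit.sigma)
    if len(lcs) < 2:
        raise FitError("bootstrap produced fewer than 2 successful refits")
    return {
        "Lc_se": float(np.std(lcs, ddof=1)),
        "sigma_se": float(np.std(sigmas, ddof=1)),
        "n_successful": len(lcs),
    }
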
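"""Synthetic datasets emulating micropatterned neurite-outgrowth experiments.

Three study designs are generated:

* **single** — one neurite per neuron guided along a microchannel
  (default n = 68 neurites over 9 dishes);
* **simultaneous** — two microchannels open from the start, two neurites
  elongate concurrently (default 18 pairs over 8 dishes);
* **stepwise** — the second channel is opened by in-situ etching after the
  first neurite has grown, decoupling elongation order from length
  (default 11 pairs over 7 dishes).

Axon labels are Bernoulli draws from the tanh length-probability sigmoid.
When a competitor is present the effective critical length is shifted up by
``competition_shift`` (default 9.9 μm, i.e. 43.3 → 53.2 μm), plus an
additional ``conditional_shift`` (default 8.8 μm, 53.2 → 62.0 μm) when the
partner's final length exceeds the single-neurite definitive length — a
phenomenological encoding of inter-neurite competition, not a mechanism.

Each labelled neurite also receives a two-channel intensity profile: a flat
baseline plus one Gaussian-shaped peak per channel along the path, with
additive Gaussian noise truncated at 0.  Axons are Tau-dominant; unlabelled
(undifferentiated) neurites show mixed expression with MAP2 moderately
dominant, so the differentiation index separates the classes when noise is
moderate and reproduces the labels exactly when noise is zero.

Reproducibility: one top-level seed; every record draws from a child stream
``SeedSequence(entropy=seed, spawn_key=(stream, record_index))`` so any
subset of records is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DEFAULT_P_DEFINITIVE, sigmoid_probability
from .quantify import (
    DEFAULT_SOMA_DIAMETER,
    apply_exclusion,
    compute_idiff,
    profile_extrema,
)

__all__ = [
    "ConfigurationError",
    "IntensityModel",
    "SyntheticConfig",
    "IntensityProfile",
    "generate_lengths",
    "generate_labels",
    "generate_profile",
    "generate_single_dataset",
    "generate_pair_dataset",
    "render_profile_images",
]

PARADIGMS = ("simultaneous", "stepwise")

# stream ids of the per-record RNG scheme
_S_LENGTHS = 0
_S_LABELS = 1
_S_PROFILE = 2
_S_CHAMBER = 3
_S_PAIR = 4


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Child RNG for stream/record ``key`` under the top-level ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class IntensityModel:
    """Two-channel fluorescence model (arbitrary units, all >= 0).

    A profile is ``baseline + amplitude * exp(-(x - 0.6 L)^2 / (2 (L/4)^2))``
    per channel plus truncated Gaussian noise.  Axons: Tau amplitude
    ``peak_axon_tau``, MAP2 amplitude ``axon_map2_ratio * peak_dendrite_map2``.
    Undifferentiated neurites: MAP2 amplitude ``peak_dendrite_map2``, Tau
    amplitude ``nonaxon_tau_ratio * peak_dendrite_map2`` (mixed expression;
    setting the ratio to 1 makes the channels exactly symmetric).
    """

    baseline: float = 20.0
    peak_axon_tau: float = 150.0
    peak_dendrite_map2: float = 150.0
    #: per-sample noise, a.u.  Kept small relative to the peak amplitudes
    #: because the channel *minimum* is an extreme order statistic over the
    #: whole profile: averaged line profiles from stained cultures show only
    #: a few percent sample-to-sample scatter, and much larger values would
    #: let noise on the minima dominate the contrast ratio.
    noise_sd: float = 3.0
    axon_map2_ratio: float = 0.3
    nonaxon_tau_ratio: float = 0.6

    def __post_init__(self) -> None:
        for name in (
            "baseline",
            "peak_axon_tau",
            "peak_dendrite_map2",
            "noise_sd",
            "axon_map2_ratio",
            "nonaxon_tau_ratio",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating truth and sampling design for synthetic datasets.

    Defaults reproduce the study conditions: single-neurite truth
    (Lc, sigma) = (43.3, 13.7) μm; lengths uniform on [10, 200] μm; n = 68
    single neurites / 18 simultaneous / 11 stepwise pairs; competition
    shifts of 9.9 and 8.8 μm.
    """

    true_Lc: float = 43.3
    true_sigma: float = 13.7
    n: int = 68
    n_pairs: int = 18
    length_range: tuple[float, float] = (10.0, 200.0)
    length_distribution: str = "uniform"
    competition_shift: float = 9.9
    conditional_shift: float = 8.8
    p_definitive: float = DEFAULT_P_DEFINITIVE
    intensity: IntensityModel = field(default_factory=IntensityModel)
    pixel_size: float = 0.5
    n_dishes: int = 9
    soma_diameter: float = DEFAULT_SOMA_DIAMETER
    #: stray in-chamber outgrowth is drawn uniform on (0, chamber_growth_max];
    #: records above 2x the soma diameter are flagged excluded.
    chamber_growth_max: float = 44.0
    retraction_prob: float = 0.2
    #: stepwise only: range of the first neurite's pre-opening length
    #: (defaults to length_range when None).
    first_length_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_sigma <= 0:
            raise ConfigurationError("true_sigma must be positive")
        lo, hi = self.length_range
        if not lo < hi:
            raise ConfigurationError("length_range must satisfy min < max")
        if self.n < 1 or self.n_pairs < 1:
            raise ConfigurationError("sample sizes must be >= 1")
        if self.length_distribution not in ("uniform", "lognormal"):
            raise ConfigurationError(
                f"unknown length_distribution {self.length_distribution!r}"
            )
        if not 0.0 <= self.retraction_prob <= 1.0:
            raise ConfigurationError("retraction_prob must lie in [0, 1]")
        if not 0.5 <= self.p_definitive < 1.0:
            raise ConfigurationError("p_definitive must lie in [0.5, 1)")
        if self.first_length_range is not None:
            flo, fhi = self.first_length_range
            if not flo < fhi:
                raise ConfigurationError("first_length_range must satisfy min < max")

    @property
    def true_Lt(self) -> float:
        """Definitive length implied by the single-neurite truth (μm)."""
        return self.true_Lc + self.true_sigma * math.atanh(
            2.0 * self.p_definitive - 1.0
        )


@dataclass
class IntensityProfile:
    """Two-channel fluorescence sampled along a neurite path.

    ``positions`` increase monotonically from the soma (μm); intensities
    are nonnegative a.u. of equal length (>= 2 samples).
    """

    positions: np.ndarray
    tau_values: np.ndarray
    map2_values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.tau_values = np.asarray(self.tau_values, dtype=float)
        self.map2_values = np.asarray(self.map2_values, dtype=float)
        n = self.positions.size
        if n < 2 or self.tau_values.size != n or self.map2_values.size != n:
            raise ValueError("profile arrays must share a length >= 2")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.tau_values.min() < 0 or self.map2_values.min() < 0:
            raise ValueError("intensities must be nonnegative")


def generate_lengths(config: SyntheticConfig, n: int | None = None) -> np.ndarray:
    """Draw i.i.d. neurite lengths from the configured distribution.

    Uniform draws directly on ``length_range``; lognormal draws (median at
    the geometric midpoint, log-sd 0.5) are rejection-truncated to the
    range.  Reproducible under the config seed.
    """
    n = config.n if n is None else int(n)
    rng = _rng(config.seed, _S_LENGTHS)
    lo, hi = config.length_range
    if config.length_distribution == "uniform":
        return rng.uniform(lo, hi, size=n)
    # lognormal, truncated by rejection
    mu = math.log(math.sqrt(lo * hi)) if lo > 0 else math.log(hi / 4.0)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mean=mu, sigma=0.5, size=max(2 * (n - filled), 16))
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def generate_labels(lengths, Lc: float, sigma: float, seed: int) -> np.ndarray:
    """Bernoulli axon labels from the sigmoid at each length (1 = axon)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    L = np.asarray(lengths, dtype=float)
    p = sigmoid_probability(L, Lc, sigma)
    rng = _rng(seed, _S_LABELS)
    return (rng.random(L.size) < p).astype(int)


def generate_profile(
    length: float,
    is_axon: bool | int,
    config: SyntheticConfig,
    record_index: int = 0,
) -> IntensityProfile:
    """Two-channel intensity profile for one neurite (~1 μm sampling)."""
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    im = config.intensity
    rng = _rng(config.seed, _S_PROFILE, record_index)
    n_samples = max(int(round(length)) + 1, 8)
    positions = np.linspace(0.0, length, n_samples)
    peak_pos = 0.6 * length
    width = max(length / 4.0, 1.0)
    shape = np.exp(-((positions - peak_pos) ** 2) / (2.0 * width**2))
    if is_axon:
        tau_amp = im.peak_axon_tau
        map2_amp = im.axon_map2_ratio * im.peak_dendrite_map2
    else:
        tau_amp = im.nonaxon_tau_ratio * im.peak_dendrite_map2
        map2_amp = im.peak_dendrite_map2
    tau = im.baseline + tau_amp * shape
    map2 = im.baseline + map2_amp * shape
    if im.noise_sd > 0:
        tau = tau + rng.normal(0.0, im.noise_sd, size=n_samples)
        map2 = map2 + rng.normal(0.0, im.noise_sd, size=n_samples)
    tau = np.clip(tau, 0.0, None)
    map2 = np.clip(map2, 0.0, None)
    return IntensityProfile(positions=positions, tau_values=tau, map2_values=map2)


_COLUMNS = [
    "neurite_id",
    "dish_id",
    "pair_id",
    "paradigm",
    "length_um",
    "tau_max",
    "tau_min",
    "map2_max",
    "map2_min",
    "soma_diameter_um",
    "chamber_length_um",
    "open_day",
    "length_at_opening_um",
    "excluded",
    "is_axon",
    "i_diff",
]


def _measurement_row(
    *,
    neurite_id: str,
    dish_id: str,
    pair_id: str,
    paradigm: str,
    length: float,
    label: int,
    config: SyntheticConfig,
    record_index: int,
    chamber_rng: np.random.Generator,
    open_day: int,
    length_at_opening: float = float("nan"),
) -> dict:
    profile = generate_profile(length, label, config, record_index=record_index)
    tau_max, tau_min, map2_max, map2_min = profile_extrema(profile)
    chamber = chamber_rng.uniform(0.0, config.chamber_growth_max)
    return {
        "neurite_id": neurite_id,
        "dish_id": dish_id,
        "pair_id": pair_id,
        "paradigm": paradigm,
        "length_um": float(length),
        "tau_max": tau_max,
        "tau_min": tau_min,
        "map2_max": map2_max,
        "map2_min": map2_min,
        "soma_diameter_um": config.soma_diameter,
        "chamber_length_um": chamber,
        "open_day": int(open_day),
        "length_at_opening_um": length_at_opening,
        "excluded": apply_exclusion(chamber, config.soma_diameter),
        "is_axon": int(label),
        "i_diff": compute_idiff(tau_max, tau_min, map2_max, map2_min),
    }


def generate_single_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Single-neurite dataset: lengths → labels → profiles → extrema.

    One row per neurite in the measurement-CSV schema, dish ids assigned
    round-robin over ``n_dishes``.
    """
    lengths = generate_lengths(config)
    labels = generate_labels(lengths, config.true_Lc, config.true_sigma, config.seed)
    chamber_rng = _rng(config.seed, _S_CHAMBER)
    rows = [
        _measurement_row(
            neurite_id=f"n{i:04d}",
            dish_id=f"dish{i % config.n_dishes + 1:02d}",
            pair_id="",
            paradigm="single",
            length=lengths[i],
            label=int(labels[i]),
            config=config,
            record_index=i,
            chamber_rng=chamber_rng,
            open_day=0,
        )
        for i in range(config.n)
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def _effective_Lc(config: SyntheticConfig, partner_length: float) -> float:
    """Critical length felt by a neurite growing against a competitor."""
    lc = config.true_Lc + config.competition_shift
    if partner_length > config.true_Lt:
        lc += config.conditional_shift
    return lc


def generate_pair_dataset(config: SyntheticConfig, paradigm: str) -> pd.DataFrame:
    """Two-neurite dataset (two rows per pair, linked by ``pair_id``).

    Simultaneous: both final lengths drawn from the configured length
    distribution.  Stepwise: the first neurite grows to a pre-opening
    length, the second channel opens 1-2 days later; with probability
    ``retraction_prob`` the first neurite retracts to a uniform fraction of
    its pre-opening length, otherwise it keeps growing modestly.  Labels
    are drawn from the sigmoid with the competition-shifted critical
    length applied to each neurite's final length.
    """
    if paradigm not in PARADIGMS:
        raise ConfigurationError(
            f"paradigm must be one of {PARADIGMS}, got {paradigm!r}"
        )
    rng = _rng(config.seed, _S_PAIR)
    chamber_rng = _rng(config.seed, _S_CHAMBER)
    lo, hi = config.length_range
    rows = []
    for k in range(config.n_pairs):
        pair_id = f"p{k:03d}"
        dish_id = f"dish{k % config.n_dishes + 1:02d}"
        if paradigm == "simultaneous":
            final = rng.uniform(lo, hi, size=2)
            open_days = (0, 0)
            length_at_opening = (float("nan"), float("nan"))
        else:
            flo, fhi = config.first_length_range or config.length_range
            pre1 = rng.uniform(flo, fhi)
            open_day_1 = 1
            open_day_2 = open_day_1 + int(rng.integers(1, 3))
            if rng.random() < config.retraction_prob:
                final1 = rng.uniform(0.0, 1.0) * pre1
            else:
                final1 = pre1 + rng.uniform(0.0, 0.3) * max(hi - pre1, 0.0)
            final2 = rng.uniform(lo, hi)
            final = np.array([final1, final2])
            open_days = (open_day_1, open_day_2)
            length_at_opening = (pre1, float("nan"))
        labels = []
        for j in range(2):
            lc_eff = _effective_Lc(config, partner_length=final[1 - j])
            p = sigmoid_probability(final[j], lc_eff, config.true_sigma)
            labels.append(int(rng.random() < p))
        for j in range(2):
            rows.append(
                _measurement_row(
                    neurite_id=f"{pair_id}_n{j + 1}",
                    dish_id=dish_id,
                    pair_id=pair_id,
                    paradigm=paradigm,
                    length=float(final[j]),
                    label=labels[j],
                    config=config,
                    record_index=2 * k + j,
                    chamber_rng=chamber_rng,
                    open_day=open_days[j],
                    length_at_opening=length_at_opening[j],
                )
            )
    return pd.DataFrame(rows, columns=_COLUMNS)


def render_profile_images(
    profile: IntensityProfile,
    pixel_size: float = 0.5,
    line_width_px: int = 2,
    margin_px: int = 8,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a profile as two 16-bit grayscale images plus path coordinates.

    The neurite is drawn as a horizontal line ``line_width_px`` pixels wide
    on a zero background; intensities are rounded to uint16.  Returns
    (tau_image, map2_image, path) where ``path`` has columns
    ``x_px, y_px`` ordered from the soma, one row per profile sample.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    xs = margin_px + np.round(profile.positions / pixel_size).astype(int)
    height = 2 * margin_px + line_width_px
    width = int(xs.max()) + margin_px + 1
    y0 = margin_px
    tau_img = np.zeros((height, width), dtype=np.uint16)
    map2_img = np.zeros((height, width), dtype=np.uint16)
    tau_px = np.clip(np.round(profile.tau_values), 0, 65535).astype(np.uint16)
    map2_px = np.clip(np.round(profile.map2_values), 0, 65535).astype(np.uint16)
    for dy in range(line_width_px):
        tau_img[y0 + dy, xs] = tau_px
        map2_img[y0 + dy, xs] = map2_px
    path = pd.DataFrame({"x_px": xs, "y_px": np.full(xs.size, y0, dtype=int)})
    return tau_img, map2_img, path


def single_neurite_config(**overrides) -> SyntheticConfig:
    """Study-condition single-neurite config (n=68, 9 dishes)."""
    return SyntheticConfig(**overrides)


def simultaneous_config(**overrides) -> SyntheticConfig:
    """Study-condition simultaneous-pair config (18 pairs, 8 dishes)."""
    base = dict(n_pairs=18, n_dishes=8)
    base.update(overrides)
    return SyntheticConfig(**base)


def stepwise_config(**overrides) -> SyntheticConfig:
    """Study-condition stepwise-pair config (11 pairs, 7 dishes)."""
    base = dict(n_pairs=11, n_dishes=7)
    base.update(overrides)
    return SyntheticConfig(**base)
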
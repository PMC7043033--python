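"""Skewed-distribution histogram parameters and mean-based color indices.

For each channel (R, G, B and gray Y) the description of a leaf is the
five-tuple (mean, median, mode, skewness, kurtosis) of its gradation-level
histogram — 20 parameters per leaf.  Skewness and kurtosis are the third and
fourth standardized central moments computed with population (biased)
normalisation; kurtosis is reported as *excess* kurtosis by default (normal
law → 0), with a ``raw`` option (normal law → 3).  The 13 color indices are
the channel means and their classical sums, differences and ratios used as
chlorophyll proxies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError
from .imaging import CHANNELS, LeafImage, PixelSample, channel_sample, to_gray

PARAM_STATS = ("Mean", "Median", "Mode", "Skewness", "Kurtosis")

#: Column order of the 20 distribution parameters in feature tables.
FEATURE_COLUMNS = [f"{c}_{s}" for c in CHANNELS for s in PARAM_STATS]

#: Column order of the 10 combination indices (the other 3 of the 13 indices
#: are R_Mean, G_Mean, B_Mean, already among the 20 parameters).
INDEX_COLUMNS = ["idx_sum", "idx_R_ratio", "idx_G_ratio", "idx_B_ratio",
                 "idx_RmG", "idx_RmB", "idx_GmB",
                 "idx_RpG", "idx_RpB", "idx_GpB"]


def _sample_values(sample) -> np.ndarray:
    if isinstance(sample, PixelSample):
        return np.asarray(sample.values)
    v = np.asarray(sample)
    if v.ndim != 1 or v.size < 1:
        raise DegenerateInputError("sample must be a non-empty 1-D sequence")
    return v


def _sample_channel(sample, default: str = "Y") -> str:
    return sample.channel if isinstance(sample, PixelSample) else default


@dataclass(frozen=True)
class ChannelHistogram:
    """Per-level pixel counts of one channel; 256 bins indexed by gradation level."""

    channel: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (256,) or (c < 0).any():
            raise InputError("counts must be 256 non-negative integers")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def cumulative(self) -> np.ndarray:
        """Running sum of counts over gradation levels (cumulative frequency view)."""
        return np.cumsum(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"level": np.arange(256),
                             "count": self.counts,
                             "cumulative": self.cumulative()})


def histogram(sample) -> ChannelHistogram:
    """Count pixels per gradation level (0–255)."""
    v = _sample_values(sample).astype(np.int64)
    if v.min() < 0 or v.max() > 255:
        raise InputError("gradation levels must lie in [0, 255]")
    counts = np.bincount(v, minlength=256)
    return ChannelHistogram(channel=_sample_channel(sample), counts=counts)


@dataclass(frozen=True)
class SkewedParams:
    """The five distribution parameters of one channel.

    ``skewness``/``kurtosis`` are NaN (and ``degenerate`` is True) for
    zero-variance samples, where they are undefined.
    """

    channel: str
    mean: float
    median: float
    mode: int
    skewness: float
    kurtosis: float
    kurtosis_convention: str = "excess"

    @property
    def degenerate(self) -> bool:
        return math.isnan(self.skewness)

    def as_row(self) -> Dict[str, float]:
        return {f"{self.channel}_Mean": self.mean,
                f"{self.channel}_Median": self.median,
                f"{self.channel}_Mode": float(self.mode),
                f"{self.channel}_Skewness": self.skewness,
                f"{self.channel}_Kurtosis": self.kurtosis}


def skewed_params(sample, kurtosis_convention: str = "excess") -> SkewedParams:
    """Mean, median, mode, skewness and kurtosis of a gradation sample.

    Central moments use population normalisation m_k = Σ(v − mean)^k / n (no
    small-sample bias correction): skewness g1 = m3 / m2^1.5 and kurtosis
    m4 / m2² − 3 (``excess``, default) or m4 / m2² (``raw``).  The mode is the
    most frequent integer level, smallest level on ties; the median follows
    the standard even/odd order-statistic rule and may be non-integer.
    """
    if kurtosis_convention not in ("excess", "raw"):
        raise InputError(f"unknown kurtosis convention {kurtosis_convention!r}")
    v = _sample_values(sample).astype(np.float64)
    n = v.size
    mean = float(v.mean())
    median = float(np.median(v))
    iv = _sample_values(sample).astype(np.int64)
    if iv.min() < 0 or iv.max() > 255:
        raise InputError("gradation levels must lie in [0, 255]")
    mode = int(np.argmax(np.bincount(iv, minlength=256)))  # argmax → smallest on ties

    d = v - mean
    m2 = float(np.mean(d * d))
    if n < 2 or m2 == 0.0:
        skew = kurt = float("nan")
    else:
        m3 = float(np.mean(d ** 3))
        m4 = float(np.mean(d ** 4))
        skew = m3 / m2 ** 1.5
        kurt = m4 / (m2 * m2)
        if kurtosis_convention == "excess":
            kurt -= 3.0
    return SkewedParams(channel=_sample_channel(sample), mean=mean, median=median,
                        mode=mode, skewness=skew, kurtosis=kurt,
                        kurtosis_convention=kurtosis_convention)


@dataclass(frozen=True)
class ColorIndices:
    """The 13 mean-based color indices: the channel means plus their classical combinations."""

    r_mean: float
    g_mean: float
    b_mean: float
    sum_rgb: float
    r_ratio: float
    g_ratio: float
    b_ratio: float
    r_minus_g: float
    r_minus_b: float
    g_minus_b: float
    r_plus_g: float
    r_plus_b: float
    g_plus_b: float

    def as_row(self) -> Dict[str, float]:
        return {"idx_sum": self.sum_rgb,
                "idx_R_ratio": self.r_ratio,
                "idx_G_ratio": self.g_ratio,
                "idx_B_ratio": self.b_ratio,
                "idx_RmG": self.r_minus_g,
                "idx_RmB": self.r_minus_b,
                "idx_GmB": self.g_minus_b,
                "idx_RpG": self.r_plus_g,
                "idx_RpB": self.r_plus_b,
                "idx_GpB": self.g_plus_b}


def color_indices(r_mean: float, g_mean: float, b_mean: float) -> ColorIndices:
    """All 13 indices from the three channel means.

    The three ratio indices sum to 1 by construction; they are NaN when
    R + G + B = 0, where they are undefined.
    """
    for name, m in (("r_mean", r_mean), ("g_mean", g_mean), ("b_mean", b_mean)):
        if not math.isfinite(m):
            raise InputError(f"{name} must be finite")
    s = r_mean + g_mean + b_mean
    if s > 0:
        rr, gr, br = r_mean / s, g_mean / s, b_mean / s
    else:
        rr = gr = br = float("nan")
    return ColorIndices(r_mean=r_mean, g_mean=g_mean, b_mean=b_mean, sum_rgb=s,
                        r_ratio=rr, g_ratio=gr, b_ratio=br,
                        r_minus_g=r_mean - g_mean, r_minus_b=r_mean - b_mean,
                        g_minus_b=g_mean - b_mean, r_plus_g=r_mean + g_mean,
                        r_plus_b=r_mean + b_mean, g_plus_b=g_mean + b_mean)


@dataclass
class LeafFeatureRecord:
    """One leaf: identity, age, optional SPAD, 20 parameters and 13 indices."""

    leaf_id: str
    age_days: Optional[float]
    spad: Optional[float]
    params: Dict[str, SkewedParams]
    indices: ColorIndices

    def __post_init__(self) -> None:
        if set(self.params) != set(CHANNELS):
            raise InputError("record must hold exactly one SkewedParams per channel R, G, B, Y")

    def to_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {"leaf_id": self.leaf_id, "age_days": self.age_days,
                                  "SPAD": self.spad}
        for c in CHANNELS:
            row.update(self.params[c].as_row())
        row.update(self.indices.as_row())
        return row


def extract_features(image: LeafImage, leaf_id: str, age_days: Optional[float] = None,
                     spad: Optional[float] = None,
                     kurtosis_convention: str = "excess") -> LeafFeatureRecord:
    """Compute all 20 distribution parameters and 13 indices of a masked leaf image."""
    params: Dict[str, SkewedParams] = {}
    for c in ("R", "G", "B"):
        params[c] = skewed_params(channel_sample(image, c), kurtosis_convention)
    params["Y"] = skewed_params(to_gray(image), kurtosis_convention)
    idx = color_indices(params["R"].mean, params["G"].mean, params["B"].mean)
    return LeafFeatureRecord(leaf_id=leaf_id, age_days=age_days, spad=spad,
                             params=params, indices=idx)


def records_to_frame(records: Iterable[LeafFeatureRecord]) -> pd.DataFrame:
    """Stack records into a DataFrame with the stable public column order."""
    rows: List[Dict[str, object]] = [r.to_row() for r in records]
    frame = pd.DataFrame(rows)
    order = ["leaf_id", "age_days", "SPAD"] + FEATURE_COLUMNS + INDEX_COLUMNS
    return frame[order]
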
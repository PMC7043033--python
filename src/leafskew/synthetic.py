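"""Synthetic leaf images with known skewed channel laws, and paired SPAD values.

Real leaf-channel histograms are skewed, with location drifting and skewness
falling from positive to negative as the leaf ages.  The generator emulates
exactly that at the level the analysis sees — the marginal gradation
distribution per channel — by drawing each masked pixel independently from a
skew-normal law (R, G) or a scaled beta law (B, whose printed skewness of
1.5–2.1 exceeds the skew-normal maximum |γ1| ≈ 0.995), then rounding and
clipping to integer levels.  SPAD is linked to the realized features through
one of the published models plus Gaussian noise.  Closed-form law moments are
exposed as the oracle against which extracted features are checked.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InputError
from .features import LeafFeatureRecord, extract_features, records_to_frame
from .imaging import LeafImage, round_half_away_from_zero, save_leaf_png
from .modeling import predict_published

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)
#: Supremum of |skewness| reachable by a skew-normal law.
MAX_SKEW_NORMAL_SKEWNESS = 0.5 * (4.0 - math.pi) * _SQRT_2_OVER_PI ** 3 \
    / (1.0 - _SQRT_2_OVER_PI ** 2) ** 1.5


@dataclass(frozen=True)
class SkewNormalLaw:
    """Skew-normal SN(ξ, ω, α): location, scale, shape."""
    xi: float
    omega: float
    alpha: float

    def __post_init__(self):
        if self.omega <= 0:
            raise InputError("skew-normal scale omega must be positive")


@dataclass(frozen=True)
class BetaLaw:
    """Beta(a, b) linearly mapped onto [lo, hi] (gradation range by default)."""
    a: float
    b: float
    lo: float = 0.0
    hi: float = 255.0

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0 or self.hi <= self.lo:
            raise InputError("beta law needs a, b > 0 and hi > lo")


@dataclass(frozen=True)
class PointMassLaw:
    """Degenerate law: every pixel takes ``value``."""
    value: float


Law = Union[SkewNormalLaw, BetaLaw, PointMassLaw]


@dataclass(frozen=True)
class Moments:
    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float


def analytic_moments(law: Law) -> Moments:
    """Closed-form mean, SD, skewness and excess kurtosis of a channel law.

    These describe the continuous law *before* discretization; rounding to
    integer levels perturbs them by well under 0.02 in skewness for scales
    ω >= 10 with negligible mass outside [0, 255] (asserted empirically in
    the test suite).
    """
    if isinstance(law, PointMassLaw):
        return Moments(law.value, 0.0, float("nan"), float("nan"))
    if isinstance(law, SkewNormalLaw):
        delta = law.alpha / math.sqrt(1.0 + law.alpha ** 2)
        mz = delta * _SQRT_2_OVER_PI
        var_z = 1.0 - mz * mz
        skew = 0.5 * (4.0 - math.pi) * mz ** 3 / var_z ** 1.5
        kurt = 2.0 * (math.pi - 3.0) * mz ** 4 / var_z ** 2
        return Moments(law.xi + law.omega * mz, law.omega * math.sqrt(var_z), skew, kurt)
    if isinstance(law, BetaLaw):
        a, b = law.a, law.b
        mean01 = a / (a + b)
        var01 = a * b / ((a + b) ** 2 * (a + b + 1.0))
        skew = 2.0 * (b - a) * math.sqrt(a + b + 1.0) / ((a + b + 2.0) * math.sqrt(a * b))
        kurt = 6.0 * ((a - b) ** 2 * (a + b + 1.0) - a * b * (a + b + 2.0)) \
            / (a * b * (a + b + 2.0) * (a + b + 3.0))
        scale = law.hi - law.lo
        return Moments(law.lo + scale * mean01, scale * math.sqrt(var01), skew, kurt)
    raise InputError(f"unknown law {law!r}")


def sample_law(law: Law, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n continuous values from a channel law."""
    if isinstance(law, PointMassLaw):
        return np.full(n, float(law.value))
    if isinstance(law, SkewNormalLaw):
        delta = law.alpha / math.sqrt(1.0 + law.alpha ** 2)
        z0 = rng.standard_normal(n)
        z1 = rng.standard_normal(n)
        z = delta * np.abs(z0) + math.sqrt(1.0 - delta * delta) * z1
        return law.xi + law.omega * z
    if isinstance(law, BetaLaw):
        return law.lo + (law.hi - law.lo) * rng.beta(law.a, law.b, n)
    raise InputError(f"unknown law {law!r}")


# --------------------------------------------------------------------------
# Solving law parameters from target moments
# --------------------------------------------------------------------------

def skew_normal_from_moments(mean: float, sd: float, skewness: float) -> SkewNormalLaw:
    """Skew-normal law with the given mean, SD and skewness (|γ1| < 0.9953)."""
    if sd <= 0:
        raise InputError("sd must be positive")
    g = abs(skewness)
    if g >= MAX_SKEW_NORMAL_SKEWNESS:
        raise InputError(
            f"|skewness| {g:.3f} exceeds the skew-normal maximum "
            f"{MAX_SKEW_NORMAL_SKEWNESS:.4f}; use a beta law instead")
    if g == 0.0:
        return SkewNormalLaw(xi=mean, omega=sd, alpha=0.0)

    def gamma1(delta: float) -> float:
        mz = delta * _SQRT_2_OVER_PI
        return 0.5 * (4.0 - math.pi) * mz ** 3 / (1.0 - mz * mz) ** 1.5

    delta = optimize.brentq(lambda d: gamma1(d) - g, 1e-12, 1.0 - 1e-12, xtol=1e-14)
    if skewness < 0:
        delta = -delta
    mz = delta * _SQRT_2_OVER_PI
    omega = sd / math.sqrt(1.0 - mz * mz)
    alpha = delta / math.sqrt(1.0 - delta * delta)
    return SkewNormalLaw(xi=mean - omega * mz, omega=omega, alpha=alpha)


def beta_from_mean_skewness(mean: float, skewness: float,
                            lo: float = 0.0, hi: float = 255.0) -> BetaLaw:
    """Beta law matching a target mean and (positive) skewness.

    The mean pins the ratio b/a; skewness is then monotone decreasing in a and
    is solved by bisection.  At a fixed support the reachable skewness is
    bounded above by (r − 1)/√r with r = b/a, so when the target exceeds that
    bound the upper support limit is widened (the law stays concentrated far
    below the gradation ceiling; the widened support is accepted only if it
    leaves < 0.1% of mass above ``hi`` of the gradation range, so clipping
    bias stays negligible).
    """
    if skewness <= 0:
        raise InputError("beta solver expects positive target skewness")
    from scipy import stats as sps
    grad_hi = hi
    best: Optional[Tuple[float, BetaLaw]] = None
    for factor in (1.0, 1.25, 1.6, 2.0, 3.0, 4.0, 6.0, 10.0, 20.0):
        hi_try = factor * hi
        mu = (mean - lo) / (hi_try - lo)
        if not 0.0 < mu < 0.5:
            continue
        ratio = (1.0 - mu) / mu  # b = ratio * a
        max_skew = (ratio - 1.0) / math.sqrt(ratio)  # a -> 0 limit
        if skewness >= 0.98 * max_skew:
            continue

        def f(a: float) -> float:
            return analytic_moments(BetaLaw(a, ratio * a, lo, hi_try)).skewness - skewness

        a = optimize.brentq(f, 1e-9, 1e9, xtol=1e-12)
        law = BetaLaw(a=a, b=ratio * a, lo=lo, hi=hi_try)
        tail = float(sps.beta.sf((grad_hi - lo) / (hi_try - lo), law.a, law.b))
        if tail < 1e-3:
            return law
        if best is None or tail < best[0]:
            best = (tail, law)
    # Very skewed targets (printed 65-day blue channel) leave ~0.2% of any
    # smooth right-skewed law above the gradation ceiling; real histograms
    # are clipped there too, so accept the mildest such law.
    if best is not None and best[0] < 1e-2:
        return best[1]
    raise InputError(
        f"no beta law with mean {mean:g} and skewness {skewness:g} fits the "
        f"gradation range with acceptable clipping")


# --------------------------------------------------------------------------
# Single-leaf generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticLeafSpec:
    """Recipe for one leaf image: canvas, elliptical blade, per-channel laws, seed."""

    laws: Mapping[str, Law]          # keys "R", "G", "B"
    seed: int
    width: int = 500
    height: int = 665
    axes: Tuple[float, float] = (0.9, 0.9)   # ellipse axes as canvas fractions

    def __post_init__(self):
        if set(self.laws) != {"R", "G", "B"}:
            raise InputError("laws must be given for exactly R, G and B")
        if not (0 < self.axes[0] <= 1 and 0 < self.axes[1] <= 1):
            raise InputError("ellipse axes must be canvas fractions in (0, 1]")
        if self.seed is None:
            raise InputError("a seed is mandatory")


def _ellipse_mask(width: int, height: int, axes: Tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    ax, ay = axes[0] * width / 2.0, axes[1] * height / 2.0
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def generate_leaf(spec: SyntheticLeafSpec) -> LeafImage:
    """Render a leaf: elliptical mask, i.i.d. channel draws, round + clip to [0, 255].

    Bit-reproducible from the seed.  Warns if more than 0.1% of a channel's
    continuous mass falls outside the gradation range, where clipping would
    bias the realized moments.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipse_mask(spec.width, spec.height, spec.axes)
    n = int(mask.sum())
    rasters = {}
    for ch in ("R", "G", "B"):
        vals = sample_law(spec.laws[ch], n, rng)
        frac_out = float(np.mean((vals < -0.5) | (vals > 255.5)))
        if frac_out > 1e-3:
            warnings.warn(f"channel {ch}: {frac_out:.2%} of mass outside [0, 255]; "
                          "clipping will bias the moments")
        q = np.clip(round_half_away_from_zero(vals), 0, 255).astype(np.uint8)
        raster = np.zeros(mask.shape, dtype=np.uint8)
        raster[mask] = q
        rasters[ch] = raster
    return LeafImage(red=rasters["R"], green=rasters["G"], blue=rasters["B"], mask=mask)


# --------------------------------------------------------------------------
# Age profiles and dataset generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelTarget:
    """Moment targets for one channel at one age; ``sd`` is ignored by the beta law."""
    mean: float
    sd: float
    skewness: float


@dataclass(frozen=True)
class AgeProfile:
    """Study design: per-age channel-moment targets and the SPAD link.

    ``leaf_mean_sd`` jitters each leaf's channel mean around the age target
    (between-leaf variability); ``leaf_skewness_sd`` does the same for the
    shape.  SPAD = published-model prediction on the realized features plus
    N(0, noise_sd²).
    """

    targets: Mapping[int, Mapping[str, ChannelTarget]]
    spad_link: str = "F1"
    noise_sd: float = 1.5
    leaf_mean_sd: float = 4.0
    leaf_skewness_sd: float = 0.05

    @property
    def ages(self) -> Tuple[int, ...]:
        return tuple(sorted(self.targets))


def default_age_profile(**overrides) -> AgeProfile:
    """Four-age profile tracking the published per-age channel means/skewness.

    Channel means rise with age while skewness falls from positive to
    negative (R, G); the blue channel stays low-mean and strongly
    right-skewed.  Within-age SDs are not published; ~20 gradation levels
    (R), 18 (G) is typical of single-leaf channel spreads.
    """
    t = {
        40: {"R": ChannelTarget(98.64, 20.0, 0.46),
             "G": ChannelTarget(126.58, 18.0, 0.35),
             "B": ChannelTarget(32.60, 0.0, 1.83)},
        50: {"R": ChannelTarget(102.38, 20.0, -0.04),
             "G": ChannelTarget(126.98, 18.0, -0.29),
             "B": ChannelTarget(37.34, 0.0, 1.48)},
        60: {"R": ChannelTarget(121.78, 20.0, -0.19),
             "G": ChannelTarget(138.96, 18.0, -0.36),
             "B": ChannelTarget(39.65, 0.0, 1.65)},
        65: {"R": ChannelTarget(154.62, 20.0, -0.59),
             "G": ChannelTarget(149.80, 18.0, -0.59),
             "B": ChannelTarget(44.82, 0.0, 2.10)},
    }
    return AgeProfile(targets=t, **overrides)


def law_from_target(channel: str, target: ChannelTarget) -> Law:
    """Channel law realizing a moment target: beta for B, skew-normal otherwise."""
    if channel == "B":
        return beta_from_mean_skewness(target.mean, target.skewness)
    return skew_normal_from_moments(target.mean, target.sd, target.skewness)


@dataclass
class SyntheticDataset:
    """Output of :func:`generate_dataset`: feature records plus optional images."""

    records: List[LeafFeatureRecord]
    images: Optional[List[LeafImage]]
    profile: AgeProfile
    seed: int

    @property
    def frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def generate_dataset(profile: AgeProfile, leaves_per_age: int = 50, seed: int = 0,
                     canvas: Tuple[int, int] = (500, 665),
                     axes: Tuple[float, float] = (0.9, 0.9),
                     keep_images: bool = False,
                     out_dir: Optional[Path] = None) -> SyntheticDataset:
    """Generate a full multi-age leaf set with paired SPAD values.

    Per-leaf sub-seeds derive deterministically from the master seed, so two
    runs with the same arguments are bit-identical.  With ``out_dir`` set,
    each leaf is written as an RGBA PNG (background alpha = 0) alongside a
    ``manifest.csv`` mapping leaf ids to image paths, ages and SPAD values.
    """
    master = np.random.SeedSequence(seed)
    records: List[LeafFeatureRecord] = []
    images: Optional[List[LeafImage]] = [] if keep_images else None
    manifest_rows = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    for age in profile.ages:
        for i in range(leaves_per_age):
            child = master.spawn(1)[0]
            leaf_seed = int(child.generate_state(1)[0] % (2 ** 31))
            jrng = np.random.default_rng(child)
            laws: Dict[str, Law] = {}
            for ch in ("R", "G", "B"):
                tgt = profile.targets[age][ch]
                # blue sits at ~1/3 the level of R/G; scale its spread down
                mean_sd = profile.leaf_mean_sd * (0.5 if ch == "B" else 1.0)
                mean = tgt.mean + jrng.normal(0.0, mean_sd)
                skew = tgt.skewness + jrng.normal(0.0, profile.leaf_skewness_sd)
                if ch == "B":
                    # stay inside the envelope where a beta law keeps the
                    # mass above the gradation ceiling negligible
                    skew = min(max(skew, 0.05), 2.15)
                    mean = min(max(mean, 5.0), 49.0)
                else:
                    lim = MAX_SKEW_NORMAL_SKEWNESS - 1e-3
                    skew = min(max(skew, -lim), lim)
                laws[ch] = law_from_target(ch, replace(tgt, mean=mean, skewness=skew))
            spec = SyntheticLeafSpec(laws=laws, seed=leaf_seed,
                                     width=canvas[0], height=canvas[1], axes=axes)
            image = generate_leaf(spec)
            leaf_id = f"age{age}_leaf{i:03d}"
            rec = extract_features(image, leaf_id=leaf_id, age_days=float(age))
            spad = float(predict_published(profile.spad_link, rec))
            if profile.noise_sd > 0:
                spad += float(jrng.normal(0.0, profile.noise_sd))
            rec.spad = spad
            records.append(rec)
            if images is not None:
                images.append(image)
            if out_dir is not None:
                path = out_dir / f"{leaf_id}.png"
                save_leaf_png(image, path)
                manifest_rows.append({"leaf_id": leaf_id, "age_days": age,
                                      "SPAD": spad, "image": path.name})

    if out_dir is not None:
        pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.csv", index=False)
    return SyntheticDataset(records=records, images=images, profile=profile, seed=seed)
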
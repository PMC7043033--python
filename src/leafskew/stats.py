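"""Normality tests, correlation with significance stars, Duncan letter display.

The Lilliefors test (Kolmogorov–Smirnov against a normal law with estimated
mean and SD) cannot use the plain KS null distribution; its p-values here come
from a Monte-Carlo-calibrated critical-value table shipped with the package
(20,000 null replicates per sample-size grid point, fixed seed; see
``scripts/make_lilliefors_table.py`` in the repository).  Reported p-values
are clipped to the conventional tabulated range [0.001, 0.5].

The Jarque–Bera statistic is JB = (n/6)·(S² + (K − 3)²/4) with S and K the
biased sample skewness and *raw* kurtosis, referred to its asymptotic χ²(2)
law — adequate at the pixel-scale sample sizes this package targets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, InputError
from .features import FEATURE_COLUMNS, INDEX_COLUMNS, LeafFeatureRecord, records_to_frame
from .imaging import PixelSample

P_CLIP_LO = 0.001
P_CLIP_HI = 0.5


def _values(sample) -> np.ndarray:
    if isinstance(sample, PixelSample):
        return np.asarray(sample.values, dtype=np.float64)
    v = np.asarray(sample, dtype=np.float64)
    if v.ndim != 1:
        raise InputError("sample must be 1-D")
    return v


@dataclass(frozen=True)
class NormalityResult:
    method: str
    statistic: float
    p_value: float
    alpha: float
    reject: bool


def jarque_bera_statistic(n: int, skewness: float, raw_kurtosis: float) -> float:
    """JB = (n/6)·(S² + (K − 3)²/4)."""
    return (n / 6.0) * (skewness ** 2 + (raw_kurtosis - 3.0) ** 2 / 4.0)


def jarque_bera(sample, alpha: float = 0.05) -> NormalityResult:
    """Jarque–Bera normality test with the asymptotic χ²(2) p-value."""
    v = _values(sample)
    n = v.size
    if n < 8:
        raise InputError("Jarque-Bera requires n >= 8")
    d = v - v.mean()
    m2 = float(np.mean(d * d))
    if m2 == 0.0:
        raise DegenerateInputError("zero variance: JB statistic undefined")
    s = float(np.mean(d ** 3)) / m2 ** 1.5
    k = float(np.mean(d ** 4)) / (m2 * m2)
    jb = jarque_bera_statistic(n, s, k)
    p = float(sps.chi2.sf(jb, 2))
    return NormalityResult("jarque_bera", jb, p, alpha, p < alpha)


def lilliefors_statistic(sample) -> float:
    """D = sup_x |F_n(x) − Φ((x − x̄)/s)| with s the n−1 sample SD."""
    v = np.sort(_values(sample))
    n = v.size
    if n < 4:
        raise InputError("Lilliefors requires n >= 4")
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("zero variance: Lilliefors statistic undefined")
    cdf = sps.norm.cdf((v - v.mean()) / sd)
    i = np.arange(1, n + 1, dtype=np.float64)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


_TABLE: Optional[dict] = None


def _lilliefors_table() -> dict:
    global _TABLE
    if _TABLE is None:
        with resources.files("leafskew.data").joinpath("lilliefors_table.json").open() as fh:
            raw = json.load(fh)
        raw["n"] = np.asarray(raw["n"], dtype=np.float64)
        raw["alphas"] = np.asarray(raw["alphas"], dtype=np.float64)
        raw["crit"] = np.asarray(raw["crit"], dtype=np.float64)
        _TABLE = raw
    return _TABLE


def _critical_values(n: int) -> np.ndarray:
    """Critical values at every tabulated significance level, for sample size n.

    Within the calibrated grid, interpolation is linear in 1/sqrt(n) (the
    statistic's asymptotic scale).  Beyond the grid the largest calibrated
    row is scaled by sqrt(n_max/n).
    """
    tab = _lilliefors_table()
    ns, crit = tab["n"], tab["crit"]
    if n >= ns[-1]:
        return crit[-1] * math.sqrt(ns[-1] / n)
    s = 1.0 / np.sqrt(ns)
    order = np.argsort(s)
    sq = 1.0 / math.sqrt(n)
    return np.array([np.interp(sq, s[order], crit[order, j])
                     for j in range(crit.shape[1])])


def lilliefors_critical_value(n: int, alpha: float) -> float:
    """Calibrated critical value of D at significance level ``alpha``."""
    tab = _lilliefors_table()
    alphas = tab["alphas"]
    cvs = _critical_values(n)
    order = np.argsort(alphas)
    return float(np.interp(alpha, alphas[order], cvs[order]))


def _lilliefors_pvalue(d: float, n: int) -> float:
    tab = _lilliefors_table()
    alphas = tab["alphas"]
    cvs = _critical_values(n)
    # cv decreases as alpha increases; interpolate log(alpha) against cv.
    order = np.argsort(cvs)
    if d >= cvs[order][-1]:
        return P_CLIP_LO
    if d <= cvs[order][0]:
        return P_CLIP_HI
    logp = np.interp(d, cvs[order], np.log(alphas[order]))
    return float(min(max(math.exp(logp), P_CLIP_LO), P_CLIP_HI))


def lilliefors(sample, alpha: float = 0.05) -> NormalityResult:
    """Lilliefors normality test with Monte-Carlo-calibrated, clipped p-values."""
    d = lilliefors_statistic(sample)
    n = _values(sample).size
    p = _lilliefors_pvalue(d, n)
    return NormalityResult("lilliefors", d, p, alpha, p < alpha)


# --------------------------------------------------------------------------
# Correlation with significance stars
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationEntry:
    feature: str
    r: float
    p_value: float
    stars: str
    n: int


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlate(features, target: str = "SPAD",
              feature_names: Optional[Sequence[str]] = None) -> List[CorrelationEntry]:
    """Pearson correlation of each feature with the target, with 0.05/0.01 stars.

    ``features`` is a DataFrame or an iterable of :class:`LeafFeatureRecord`.
    Two-tailed p-values come from the t distribution with n − 2 df.  Constant
    features yield r = NaN with no stars rather than an error.
    """
    if not isinstance(features, pd.DataFrame):
        features = records_to_frame(features)
    if target not in features.columns:
        raise InputError(f"target column {target!r} not present")
    if feature_names is None:
        feature_names = [c for c in FEATURE_COLUMNS + INDEX_COLUMNS if c in features.columns]
    out: List[CorrelationEntry] = []
    y_all = features[target].to_numpy(dtype=np.float64)
    for name in feature_names:
        x_all = features[name].to_numpy(dtype=np.float64)
        ok = np.isfinite(x_all) & np.isfinite(y_all)
        x, y = x_all[ok], y_all[ok]
        n = x.size
        if n < 3:
            raise InputError(f"need >= 3 finite records for {name!r}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(CorrelationEntry(name, float("nan"), float("nan"), "", n))
            continue
        r, p = sps.pearsonr(x, y)
        out.append(CorrelationEntry(name, float(r), float(p), _stars(float(p)), n))
    return out


def correlation_frame(entries: Iterable[CorrelationEntry]) -> pd.DataFrame:
    return pd.DataFrame([{"feature": e.feature, "r": e.r, "p_value": e.p_value,
                          "stars": e.stars, "n": e.n} for e in entries])


# --------------------------------------------------------------------------
# Duncan multiple range test and compact letter display
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LetterDisplay:
    """Group labels and means sorted ascending, with Duncan letters.

    Groups sharing a letter are not significantly different at ``alpha``.
    """

    labels: Tuple
    means: Tuple[float, ...]
    letters: Tuple[str, ...]
    alpha: float

    def as_dict(self) -> Dict:
        return dict(zip(self.labels, self.letters))


def duncan_letters(groups: Mapping, alpha: float = 0.05) -> LetterDisplay:
    """Duncan's multiple range test with a compact letter display.

    One-way ANOVA supplies the pooled MSE; the least significant range for a
    span of p ordered means uses the studentized-range quantile at Duncan's
    protection level 1 − (1 − α)^(p−1).  Unequal group sizes are handled via
    the harmonic mean size.  Letters are assigned to maximal runs of ordered
    means whose range does not exceed the corresponding least significant
    range (non-significant subranges of such a run are declared
    non-significant, per the step-down protocol).
    """
    items = [(lab, np.asarray(v, dtype=np.float64)) for lab, v in groups.items()]
    k = len(items)
    if k < 2:
        raise InputError("Duncan test requires >= 2 groups")
    if any(v.size < 2 for _, v in items):
        raise InputError("every group needs n >= 2")
    ns = np.array([v.size for _, v in items], dtype=np.float64)
    means = np.array([v.mean() for _, v in items])
    big_n = ns.sum()
    dfe = int(big_n - k)
    mse = float(sum((v.size - 1) * v.var(ddof=1) for _, v in items) / dfe)
    nh = k / float(np.sum(1.0 / ns))

    order = np.argsort(means, kind="stable")
    m_sorted = means[order]
    labels_sorted = tuple(items[i][0] for i in order)

    lsr = np.zeros(k + 1)
    for span in range(2, k + 1):
        a_p = 1.0 - (1.0 - alpha) ** (span - 1)
        q = float(sps.studentized_range.ppf(1.0 - a_p, span, dfe))
        lsr[span] = q * math.sqrt(mse / nh)

    tol = 1e-12 * max(1.0, float(np.max(np.abs(m_sorted))))

    def nonsig(i: int, j: int) -> bool:
        return (m_sorted[j] - m_sorted[i]) <= lsr[j - i + 1] + tol

    # maximal non-significant runs -> letters
    intervals: List[Tuple[int, int]] = []
    for i in range(k):
        j_max = i
        for j in range(i + 1, k):
            if nonsig(i, j):
                j_max = j
        intervals.append((i, j_max))
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)]
    # dedupe while preserving order
    seen = set()
    maximal = [iv for iv in maximal if not (iv in seen or seen.add(iv))]

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for idx, (lo, hi) in enumerate(sorted(maximal)):
        ch = alphabet[idx % len(alphabet)]
        for g in range(lo, hi + 1):
            letters[g] += ch
    return LetterDisplay(labels=labels_sorted, means=tuple(float(m) for m in m_sorted),
                         letters=tuple(letters), alpha=alpha)
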
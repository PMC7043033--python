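"""SPAD association models: stepwise linear, single-term Fourier, cubic surface.

Four model families link leaf-color features to the SPAD chlorophyll reading:

* ``linear_stepwise`` — multivariate OLS built by classic forward selection
  with backward elimination on partial-F p-values (enter 0.05, remove 0.10);
* ``fourier1`` — y = a0 + a1·cos(w·x) + b1·sin(w·x), fitted by a multistart
  frequency grid with an exact linear subproblem for (a0, a1, b1);
* ``poly_surface`` — bivariate cubic least squares over monomials x1^i·x2^j.

The published reference models F1–F4 (with their printed coefficients) are
exposed as ready-made predictors, along with their published goodness-of-fit
table.  Evaluation reports R², adjusted R², SSE, RMSE and per-sample
predictive accuracy (1 − |ŷ − y|/y)·100%.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .errors import DegenerateInputError, FitError, InputError
from .features import LeafFeatureRecord

FAMILY_LINEAR = "linear_stepwise"
FAMILY_FOURIER = "fourier1"
FAMILY_SURFACE = "poly_surface"

#: The 9 monomial powers (i, j) of the printed cubic surface (no x1³ term).
F4_TERM_POWERS: Tuple[Tuple[int, int], ...] = (
    (0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (2, 1), (1, 2), (0, 3))

#: All 10 monomials of a full bivariate cubic, i + j <= 3.
FULL_POLY33_POWERS: Tuple[Tuple[int, int], ...] = tuple(
    (i, j) for i in range(4) for j in range(4) if i + j <= 3)


@dataclass(frozen=True)
class FittedModel:
    """Coefficients plus functional form for any of the three model families.

    ``coefficients`` is keyed by predictor name (plus ``"Intercept"``) for the
    linear family and by ``a0``/``a1``/``b1``/``w`` for fourier1; the surface
    family additionally carries ``surface_powers`` aligned with
    ``surface_coefficients``, over the two predictors in order.
    """

    family: str
    predictors: Tuple[str, ...]
    coefficients: Dict[str, float] = field(default_factory=dict)
    surface_powers: Tuple[Tuple[int, int], ...] = ()
    surface_coefficients: Tuple[float, ...] = ()

    def predict(self, data) -> np.ndarray:
        """Evaluate the model on a mapping / DataFrame of named features."""
        cols = _feature_lookup(data, self.predictors)
        if self.family == FAMILY_LINEAR:
            out = np.full_like(cols[self.predictors[0]] if self.predictors
                               else np.zeros(_n_rows(data)),
                               self.coefficients.get("Intercept", 0.0), dtype=np.float64)
            if not self.predictors:
                out = np.full(_n_rows(data), self.coefficients.get("Intercept", 0.0))
            for name in self.predictors:
                out = out + self.coefficients[name] * cols[name]
            return np.asarray(out, dtype=np.float64)
        if self.family == FAMILY_FOURIER:
            x = cols[self.predictors[0]]
            c = self.coefficients
            return c["a0"] + c["a1"] * np.cos(c["w"] * x) + c["b1"] * np.sin(c["w"] * x)
        if self.family == FAMILY_SURFACE:
            x1, x2 = cols[self.predictors[0]], cols[self.predictors[1]]
            out = np.zeros(np.broadcast(x1, x2).shape, dtype=np.float64)
            for (i, j), c in zip(self.surface_powers, self.surface_coefficients):
                out = out + c * x1 ** i * x2 ** j
            return out
        raise InputError(f"unknown family {self.family!r}")

    def to_json(self) -> str:
        return json.dumps({
            "family": self.family,
            "predictors": list(self.predictors),
            "coefficients": self.coefficients,
            "surface_powers": [list(p) for p in self.surface_powers],
            "surface_coefficients": list(self.surface_coefficients)}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        d = json.loads(text)
        return cls(family=d["family"], predictors=tuple(d["predictors"]),
                   coefficients={k: float(v) for k, v in d["coefficients"].items()},
                   surface_powers=tuple((int(i), int(j)) for i, j in d["surface_powers"]),
                   surface_coefficients=tuple(float(c) for c in d["surface_coefficients"]))


def _n_rows(data) -> int:
    if isinstance(data, pd.DataFrame):
        return len(data)
    return 1


def _feature_lookup(data, names: Sequence[str]) -> Dict[str, np.ndarray]:
    """Pull named features out of a record / mapping / DataFrame."""
    if isinstance(data, LeafFeatureRecord):
        data = data.to_row()
    out: Dict[str, np.ndarray] = {}
    for name in names:
        if isinstance(data, pd.DataFrame):
            if name not in data.columns:
                raise InputError(f"required feature {name!r} missing from input")
            out[name] = data[name].to_numpy(dtype=np.float64)
        else:
            if name not in data:
                raise InputError(f"required feature {name!r} missing from input")
            out[name] = np.asarray(data[name], dtype=np.float64)
    return out


# --------------------------------------------------------------------------
# Published models (printed coefficient sets) and their published evaluation
# --------------------------------------------------------------------------

PUBLISHED_MODELS: Dict[str, FittedModel] = {
    "F1": FittedModel(FAMILY_LINEAR, ("R_Mean",),
                      {"Intercept": 59.733, "R_Mean": -0.304}),
    "F2": FittedModel(FAMILY_LINEAR, ("R_Mean", "Y_Skewness", "G_Kurtosis"),
                      {"Intercept": 76.134, "R_Mean": -0.441,
                       "Y_Skewness": -11.203, "G_Kurtosis": -1.516}),
    "F3": FittedModel(FAMILY_FOURIER, ("R_Median",),
                      {"a0": 19.38, "a1": 7.972, "b1": -6.747, "w": 1.314}),
    "F4": FittedModel(FAMILY_SURFACE, ("R_Mean", "R_Skewness"),
                      surface_powers=F4_TERM_POWERS,
                      surface_coefficients=(0.3344, 0.8709, -177.3, -0.005536,
                                            2.876, 8.515, -0.01227, -0.1398, 7.301)),
}


def predict_published(model_id: str, record) -> Union[float, np.ndarray]:
    """Evaluate one of the published models F1–F4 on a feature record.

    Trigonometric arguments of F3 are in radians.  Scalar inputs give a float.
    """
    if model_id not in PUBLISHED_MODELS:
        raise InputError(f"unknown published model {model_id!r}; choose from F1-F4")
    out = PUBLISHED_MODELS[model_id].predict(record)
    if np.ndim(out) == 0 or (isinstance(record, (LeafFeatureRecord, dict))
                             and np.size(out) == 1):
        return float(np.asarray(out).reshape(-1)[0])
    return out


@dataclass(frozen=True)
class ModelEvaluation:
    """Goodness-of-fit and prediction metrics for one model."""

    r2: float
    adjusted_r2: float
    sse: float
    rmse: float
    n: int
    n_removed: int
    accuracy_mean: float      # percent
    accuracy_sd: float        # fractional scale by default (see `evaluate`)


#: Published goodness-of-fit table for F1-F4 (training fit statistics and
#: prediction metrics on the independent 168-leaf prediction sample).
PUBLISHED_EVALUATIONS: Dict[str, ModelEvaluation] = {
    "F1": ModelEvaluation(0.583, 0.581, 7168.0, 6.017, 168, 8, 78.17, 0.1832),
    "F2": ModelEvaluation(0.694, 0.689, 5260.0, 5.181, 168, 16, 79.36, 0.1976),
    "F3": ModelEvaluation(0.648, 0.643, 6048.0, 5.555, 168, 13, 64.42, 0.2320),
    "F4": ModelEvaluation(0.719, 0.705, 4870.0, 5.050, 168, 11, 82.15, 0.1732),
}


def relative_improvement(new: float, old: float) -> float:
    """(new − old) / old, in percent."""
    return (new - old) / old * 100.0


# --------------------------------------------------------------------------
# Stepwise OLS
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StepwiseStep:
    step: int
    action: str          # "enter" | "remove"
    variable: str
    p_value: float


@dataclass(frozen=True)
class StepwiseTrace:
    steps: Tuple[StepwiseStep, ...]

    def selected(self) -> Tuple[str, ...]:
        cur: List[str] = []
        for s in self.steps:
            if s.action == "enter":
                cur.append(s.variable)
            else:
                cur.remove(s.variable)
        return tuple(cur)


_PERFECT_FIT_TOL = 1e-12
_COND_THRESHOLD = 1e8


def _ols(X: pd.DataFrame, y: np.ndarray, cols: Sequence[str]):
    design = sm.add_constant(X[list(cols)], has_constant="add")
    return sm.OLS(y, design).fit()


def _condition_number(X: pd.DataFrame, cols: Sequence[str]) -> float:
    m = sm.add_constant(X[list(cols)], has_constant="add").to_numpy(dtype=np.float64)
    norms = np.linalg.norm(m, axis=0)
    norms[norms == 0] = 1.0
    return float(np.linalg.cond(m / norms))


def stepwise_ols(X: pd.DataFrame, y, p_enter: float = 0.05, p_remove: float = 0.10
                 ) -> Tuple[FittedModel, StepwiseTrace]:
    """Forward-selection / backward-elimination OLS on partial-F p-values.

    Candidate entry uses the two-tailed p-value of the candidate's coefficient
    in the augmented model (equivalent to the partial F test); ties go to the
    smallest p then first column order.  Candidates whose addition makes the
    scaled design condition number exceed 1e8, and constant columns, are
    skipped with a warning.  Selection stops early once the fit is numerically
    perfect (SSE below 1e−12 of the total sum of squares), which makes
    noiseless coefficient-recovery runs deterministic.
    """
    y = np.asarray(y, dtype=np.float64)
    if len(X) != y.size:
        raise InputError("X and y lengths differ")
    candidates = [c for c in X.columns]
    for c in list(candidates):
        if np.ptp(X[c].to_numpy(dtype=np.float64)) == 0:
            warnings.warn(f"dropping constant candidate column {c!r}")
            candidates.remove(c)

    sst = float(np.sum((y - y.mean()) ** 2))
    selected: List[str] = []
    steps: List[StepwiseStep] = []
    step = 0
    while True:
        res_cur = _ols(X, y, selected)
        if sst == 0 or res_cur.ssr <= _PERFECT_FIT_TOL * sst:
            break  # constant target or numerically perfect fit
        # forward step
        best_name, best_p = None, math.inf
        for c in candidates:
            if c in selected:
                continue
            if _condition_number(X, selected + [c]) > _COND_THRESHOLD:
                warnings.warn(f"skipping near-collinear candidate {c!r}")
                continue
            res = _ols(X, y, selected + [c])
            p = float(res.pvalues[c])
            if math.isnan(p):
                continue
            if p < best_p:
                best_name, best_p = c, p
        entered = None
        if best_name is not None and best_p < p_enter:
            step += 1
            selected.append(best_name)
            steps.append(StepwiseStep(step, "enter", best_name, best_p))
            entered = best_name
        # backward sweep (never removes the variable just entered)
        removed_any = True
        while removed_any and len(selected) > (1 if entered else 0):
            removed_any = False
            res = _ols(X, y, selected)
            pv = {c: float(res.pvalues[c]) for c in selected if c != entered}
            if pv:
                worst = max(pv, key=pv.get)
                if pv[worst] > p_remove:
                    step += 1
                    selected.remove(worst)
                    steps.append(StepwiseStep(step, "remove", worst, pv[worst]))
                    removed_any = True
        if entered is None:
            break

    final = _ols(X, y, selected)
    coefs = {"Intercept": float(final.params["const"])}
    coefs.update({c: float(final.params[c]) for c in selected})
    model = FittedModel(FAMILY_LINEAR, tuple(selected), coefs)
    return model, StepwiseTrace(tuple(steps))


# --------------------------------------------------------------------------
# Fourier (single-harmonic) fit
# --------------------------------------------------------------------------

def _fourier_linear(x: np.ndarray, y: np.ndarray, w: float):
    design = np.column_stack([np.ones_like(x), np.cos(w * x), np.sin(w * x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid @ resid)


def fit_fourier1(x, y, w: Optional[float] = None, n_grid: Optional[int] = None,
                 predictor: str = "x") -> FittedModel:
    """Least-squares fit of y = a0 + a1·cos(w·x) + b1·sin(w·x).

    When ``w`` is free, the frequency is found by an exhaustive grid over
    [0.5·2π/range(x), 2π/Δx_min] (capped at the mean-spacing Nyquist rate),
    each grid point solved exactly for (a0, a1, b1), followed by bounded
    scalar refinement of the best local minima.  Ties in SSE resolve to the
    smallest frequency.  Passing ``w`` fixes the frequency and reduces the
    problem to linear least squares.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 5:
        raise InputError("fourier1 needs matched x, y with n >= 5")
    if np.ptp(x) == 0:
        raise InputError("x must be non-constant")

    if w is not None:
        coef, _ = _fourier_linear(x, y, w)
        return FittedModel(FAMILY_FOURIER, (predictor,),
                           {"a0": float(coef[0]), "a1": float(coef[1]),
                            "b1": float(coef[2]), "w": float(w)})

    rng_x = float(np.ptp(x))
    ux = np.unique(x)
    dx_min = float(np.min(np.diff(ux))) if ux.size > 1 else rng_x
    w_lo = math.pi / rng_x
    w_hi = min(2.0 * math.pi / dx_min, 2.0 * math.pi * x.size / rng_x)
    if n_grid is None:
        n_grid = int(np.clip(math.ceil((w_hi - w_lo) / (0.25 * math.pi / rng_x)),
                             256, 8000))
    grid = np.linspace(w_lo, w_hi, n_grid)
    sse = np.array([_fourier_linear(x, y, wg)[1] for wg in grid])
    if not np.isfinite(sse).any():
        raise FitError("fourier1: no frequency start produced a finite fit")

    # local minima of the SSE profile, best first
    interior = np.where((sse[1:-1] <= sse[:-2]) & (sse[1:-1] <= sse[2:]))[0] + 1
    starts = list(interior[np.argsort(sse[interior])][:5]) or [int(np.argmin(sse))]

    def profiled(wv: float) -> float:
        return _fourier_linear(x, y, wv)[1]

    best: Optional[Tuple[float, float]] = None  # (sse, w)
    dw = grid[1] - grid[0]
    for idx in starts:
        lo = max(w_lo * 1e-6, grid[idx] - dw)
        hi = grid[idx] + dw
        res = optimize.minimize_scalar(profiled, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-13})
        # polish: full 4-parameter Gauss-Newton from the profiled optimum
        coef0, _ = _fourier_linear(x, y, float(res.x))
        theta0 = np.array([coef0[0], coef0[1], coef0[2], float(res.x)])
        ls = optimize.least_squares(
            lambda t: t[0] + t[1] * np.cos(t[3] * x) + t[2] * np.sin(t[3] * x) - y,
            theta0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        cand = (float(2.0 * ls.cost), float(ls.x[3]))
        if best is None or cand[0] < best[0] * (1 - 1e-12) or \
                (abs(cand[0] - best[0]) <= 1e-12 * max(best[0], 1e-300) and cand[1] < best[1]):
            best = cand
    coef, _ = _fourier_linear(x, y, best[1])
    return FittedModel(FAMILY_FOURIER, (predictor,),
                       {"a0": float(coef[0]), "a1": float(coef[1]),
                        "b1": float(coef[2]), "w": best[1]})


# --------------------------------------------------------------------------
# Bivariate polynomial surface
# --------------------------------------------------------------------------

def fit_poly_surface(x1, x2, y,
                     terms: Union[str, Sequence[Tuple[int, int]]] = "exact",
                     predictors: Tuple[str, str] = ("x1", "x2")) -> FittedModel:
    """Cubic surface least squares over monomials x1^i·x2^j.

    ``terms="exact"`` (default) uses the 9-term set of the published surface
    (a full bivariate cubic minus the x1³ monomial); ``terms="full"`` uses all
    10 monomials with i + j <= 3; an explicit sequence of (i, j) powers is
    also accepted.  Columns are norm-equilibrated internally for conditioning;
    coefficients are reported on the original scale.
    """
    x1 = np.asarray(x1, dtype=np.float64).ravel()
    x2 = np.asarray(x2, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if not (x1.size == x2.size == y.size):
        raise InputError("x1, x2, y lengths differ")
    if terms == "exact":
        powers = F4_TERM_POWERS
    elif terms == "full":
        powers = FULL_POLY33_POWERS
    else:
        powers = tuple((int(i), int(j)) for i, j in terms)
    if y.size < len(powers):
        raise InputError(f"need n >= {len(powers)} points for {len(powers)} terms")

    design = np.column_stack([x1 ** i * x2 ** j for i, j in powers])
    norms = np.linalg.norm(design, axis=0)
    if (norms == 0).any():
        bad = [powers[k] for k in np.where(norms == 0)[0]]
        raise FitError(f"zero design columns for terms {bad}")
    scaled = design / norms
    rank = np.linalg.matrix_rank(scaled)
    if rank < len(powers):
        # name the offending terms via the QR pivot magnitude
        _, r = np.linalg.qr(scaled)
        bad = [powers[k] for k in np.where(np.abs(np.diag(r)) < 1e-10)[0]]
        raise FitError(f"rank-deficient design; dependent terms near {bad}")
    coef, *_ = np.linalg.lstsq(scaled, y, rcond=None)
    coef = coef / norms
    return FittedModel(FAMILY_SURFACE, predictors,
                       surface_powers=powers,
                       surface_coefficients=tuple(float(c) for c in coef))


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

def evaluate(predicted, measured, n_params: int,
             outlier_k: Optional[float] = None,
             sd_scale: str = "fraction") -> ModelEvaluation:
    """SSE, RMSE, R², adjusted R² and predictive accuracy of a prediction set.

    ``outlier_k`` optionally removes points with |standardized residual| > k
    before computing the metrics ("eliminate abnormal"); the number removed is
    reported.  Per-sample accuracy is (1 − |ŷ − y|/y)·100%, which requires
    every measured value to be positive.  Its standard deviation is reported
    on the fractional scale by default (``sd_scale="percent"`` switches).
    """
    yhat = np.asarray(predicted, dtype=np.float64).ravel()
    y = np.asarray(measured, dtype=np.float64).ravel()
    if yhat.size != y.size or y.size < 2:
        raise InputError("predicted and measured must have equal length >= 2")
    if sd_scale not in ("fraction", "percent"):
        raise InputError(f"unknown sd_scale {sd_scale!r}")

    n_removed = 0
    if outlier_k is not None:
        resid = y - yhat
        s = resid.std(ddof=1)
        if s > 0:
            z = (resid - resid.mean()) / s
            keep = np.abs(z) <= outlier_k
            n_removed = int((~keep).sum())
            yhat, y = yhat[keep], y[keep]
            if y.size < 2:
                raise DegenerateInputError("outlier removal left fewer than 2 points")

    if (y <= 0).any():
        raise DegenerateInputError("predictive accuracy undefined for measured values <= 0")

    n = y.size
    sse = float(np.sum((y - yhat) ** 2))
    rmse = math.sqrt(sse / n)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    if n - n_params - 1 > 0 and not math.isnan(r2):
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)
    else:
        adj = float("nan")
    acc = (1.0 - np.abs(yhat - y) / y) * 100.0
    acc_sd = float(acc.std(ddof=1))
    if sd_scale == "fraction":
        acc_sd /= 100.0
    return ModelEvaluation(r2=r2, adjusted_r2=adj, sse=sse, rmse=rmse, n=n,
                           n_removed=n_removed, accuracy_mean=float(acc.mean()),
                           accuracy_sd=acc_sd)
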
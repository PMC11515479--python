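"""Huber M-estimation and iterative residual-correlation term selection.

The model-building procedure couples two ideas:

* **Robust linear regression.**  Coefficients minimise the Huber loss,
  quadratic for residuals within ``k`` robust scales and linear beyond,
  fitted by iteratively reweighted least squares (IRLS) with the scale
  re-estimated each iteration as 1.4826 x the median absolute deviation
  of the current residuals.  Isolated gross blood-gas outliers therefore
  influence the fit far less than under ordinary least squares.

* **Iterative selection.**  Starting from the raw deviation between the
  PaCO2 reference and etCO2, the candidate regressor with the highest
  absolute Pearson correlation to the current deviation is added, the
  model (intercept + etCO2 + chosen terms) is refitted robustly, and the
  deviation becomes the new residual.  Selection stops when no remaining
  candidate correlates above the threshold (default 0.2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (DegenerateScaleError, DomainError, InsufficientDataError,
                     InvalidConfigError, SingularDesignError)
from .features import FORCED_TERM, CandidateDescriptor, DesignMatrix

MAD_TO_SD = 1.4826          # consistency factor for Gaussian residuals


@dataclass(frozen=True)
class FitConfig:
    """Tuning constants of the robust fit and selection loop.

    huber_k
        Huber tuning constant in robust-scale units; 1.345 gives 95%
        efficiency at the Gaussian model.
    max_iter, tol
        IRLS iteration cap and relative coefficient-change tolerance.
    corr_threshold
        Selection stops once no candidate's |Pearson r| with the current
        deviation exceeds this value.
    max_terms
        Safety cap on the number of selected terms.
    """

    huber_k: float = 1.345
    max_iter: int = 50
    tol: float = 1e-8
    corr_threshold: float = 0.2
    max_terms: int = 10

    def __post_init__(self) -> None:
        if self.huber_k <= 0:
            raise InvalidConfigError("huber_k must be positive")
        if not 0 < self.corr_threshold <= 1:
            raise InvalidConfigError("corr_threshold must be in (0, 1]")
        if self.max_iter < 1 or self.max_terms < 0:
            raise InvalidConfigError("max_iter/max_terms out of range")


@dataclass
class FittedModel:
    """Linear model: intercept plus coefficients keyed by candidate term."""

    intercept: float
    coefficients: dict[CandidateDescriptor, float]
    scale: float
    n_iter: int = 0
    converged: bool = True

    @property
    def terms(self) -> list[CandidateDescriptor]:
        return list(self.coefficients)


@dataclass
class SelectionStep:
    index: int
    chosen: CandidateDescriptor
    max_abs_r: float
    model: FittedModel


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    stop_reason: str = "threshold"      # "threshold" | "max_terms"


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; NaN when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("pearson requires equal-length vectors")
    if x.size < 3:
        raise InsufficientDataError("pearson requires at least 3 points")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt(np.dot(xd, xd)))
    sy = float(np.sqrt(np.dot(yd, yd)))
    # constant (or numerically constant) input: correlation undefined
    if sx <= 1e-12 * (1.0 + abs(float(x.mean()))) * np.sqrt(x.size):
        return float("nan")
    if sy <= 1e-12 * (1.0 + abs(float(y.mean()))) * np.sqrt(y.size):
        return float("nan")
    return float(np.dot(xd, yd) / (sx * sy))


def robust_scale(residuals: np.ndarray) -> float:
    """Robust residual scale: 1.4826 x median absolute deviation."""
    r = np.asarray(residuals, dtype=float)
    if r.size < 2:
        raise InsufficientDataError("robust_scale requires at least 2 residuals")
    mad = float(np.median(np.abs(r - np.median(r))))
    if mad == 0.0:
        raise DegenerateScaleError("median absolute deviation is zero")
    return MAD_TO_SD * mad


def huber_weights(residuals: np.ndarray, scale: float,
                  k: float = FitConfig.huber_k) -> np.ndarray:
    """IRLS weights of the Huber loss: 1 inside ``k`` scales, ``k/|u|`` beyond."""
    if scale <= 0:
        raise DegenerateScaleError("scale must be positive")
    u = np.abs(np.asarray(residuals, dtype=float)) / scale
    with np.errstate(divide="ignore"):
        return np.where(u <= k, 1.0, k / u)


def _solve_wls(A: np.ndarray, y: np.ndarray,
               w: np.ndarray | None = None) -> np.ndarray:
    if w is not None:
        sw = np.sqrt(w)
        A = A * sw[:, None]
        y = y * sw
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    return beta


def fit_huber(design: DesignMatrix, cfg: FitConfig = FitConfig()) -> FittedModel:
    """Huber IRLS fit of ``y ~ intercept + design columns``.

    Initialises with ordinary least squares and iterates weighted least
    squares until the maximum relative coefficient change falls below
    ``cfg.tol``.  If the residual MAD collapses (interpolating fit, e.g.
    noise-free data) the current solution is accepted as converged, with
    the scale floored at a tiny positive value.
    """
    X, y = design.X, design.y
    n, p = X.shape
    if n <= p + 1:
        raise InsufficientDataError(
            f"need more than {p + 1} rows to fit {p} terms, got {n}")
    A = np.column_stack([np.ones(n), X])
    beta = _solve_wls(A, y)
    scale_floor = 1e-12 * max(1.0, float(np.std(y)))
    scale = scale_floor
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        resid = y - A @ beta
        try:
            scale = robust_scale(resid)
        except DegenerateScaleError:
            scale = scale_floor          # interpolating fit
            converged = True
            break
        if scale <= 1e-8 * max(1.0, float(np.std(y))):
            converged = True             # residuals at numerical noise level
            break
        w = huber_weights(resid, scale, cfg.huber_k)
        beta_new = _solve_wls(A, y, w)
        rel = float(np.max(np.abs(beta_new - beta)
                           / np.maximum(np.abs(beta_new), 1e-10)))
        beta = beta_new
        if rel < cfg.tol:
            converged = True
            break
    if not converged:
        warnings.warn("Huber IRLS did not converge within "
                      f"{cfg.max_iter} iterations", stacklevel=2)
    try:
        scale = robust_scale(y - A @ beta)
    except DegenerateScaleError:
        scale = scale_floor
    return FittedModel(
        intercept=float(beta[0]),
        coefficients={d: float(b) for d, b in zip(design.descriptors, beta[1:])},
        scale=scale, n_iter=it, converged=converged,
    )


def restrict(design: DesignMatrix,
             terms: list[CandidateDescriptor]) -> DesignMatrix:
    """Design matrix restricted to the given columns, in the given order."""
    idx = [design.descriptors.index(t) for t in terms]
    return DesignMatrix(X=design.X[:, idx], y=design.y,
                        descriptors=list(terms),
                        sample_ids=list(design.sample_ids))


def design_prediction(model: FittedModel, design: DesignMatrix) -> np.ndarray:
    """Model prediction for every row of a design matrix."""
    out = np.full(design.X.shape[0], model.intercept)
    for term, coef in model.coefficients.items():
        out += coef * design.column(term)
    return out


def select_iteratively(full: DesignMatrix,
                       cfg: FitConfig = FitConfig()
                       ) -> tuple[FittedModel, SelectionTrace]:
    """Iterative residual-correlation term selection with robust refits.

    The iteration-0 deviation is the raw difference PaCO2 - etCO2.  At
    each step the not-yet-chosen candidate with the largest |Pearson r|
    against the current deviation is added if that correlation exceeds
    ``cfg.corr_threshold``; the model (intercept, etCO2, chosen terms) is
    refitted with :func:`fit_huber` and the deviation becomes its
    residual.  Candidates with undefined correlations (constant columns,
    or a numerically zero deviation after an exact fit) are skipped.  Ties
    resolve to the candidate earliest in catalogue order.
    """
    if FORCED_TERM not in full.descriptors:
        raise DomainError("design matrix must include the forced etCO2 column")
    y = full.y
    deviations = y - full.column(FORCED_TERM)
    pool = [d for d in full.descriptors if d != FORCED_TERM]
    chosen: list[CandidateDescriptor] = []
    trace = SelectionTrace()
    model: FittedModel | None = None
    y_scale = max(1.0, float(np.std(y)))

    while len(chosen) < cfg.max_terms:
        if float(np.std(deviations)) < 1e-9 * y_scale:
            break                        # deviation numerically zero: done
        best_desc, best_abs = None, 0.0
        for d in pool:
            r = pearson(full.column(d), deviations)
            if np.isnan(r):
                continue
            if abs(r) > best_abs + 1e-15:
                best_desc, best_abs = d, abs(r)
        if best_desc is None or best_abs <= cfg.corr_threshold:
            break
        chosen.append(best_desc)
        pool.remove(best_desc)
        model = fit_huber(restrict(full, [FORCED_TERM] + chosen), cfg)
        deviations = y - design_prediction(model, full)
        trace.steps.append(SelectionStep(index=len(trace.steps),
                                         chosen=best_desc,
                                         max_abs_r=best_abs, model=model))
    else:
        trace.stop_reason = "max_terms"

    if model is None:                    # nothing selected: base model only
        model = fit_huber(restrict(full, [FORCED_TERM]), cfg)
    return model, trace
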
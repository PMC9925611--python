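"""Cohort-based normative age modelling and W-score deviation maps.

The full-term (FT) group defines the norm.  For every structural measure a
LOESS trajectory is fitted over age (local weighted polynomial regression,
tricube weights, span optimized by bounded Brent search), the age axis is cut
into bins, and a normative mean and SD per bin and measure are computed from
the FT subjects.  Each very-preterm (VPT) subject's deviation is then the
W-score

    w = (value - mu_norm) / sigma_norm

using the norms of the subject's age bin.  W-scores are analogous to
z-scores: 0 means "on the full-term trajectory", negative means below it.

Bin assignment uses half-open intervals [lo, hi) with the last bin closed,
so the published four study bins tile 72–173 months without gaps.  A config
alternative bases W-scores on the LOESS prediction (predicted mean, residual
SD) instead of bin norms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .columns import STRUCTURAL_COLUMNS
from .data_model import StructuralTable

logger = logging.getLogger(__name__)

#: Bin edges of the four published study bins (months); half-open convention
#: puts 96.5 in bin 1 and 96.6 in bin 2, exactly as listed.
STUDY_BIN_EDGES = (72.0, 96.6, 122.1, 148.1, 173.0)

SPAN_BOUNDS = (0.05, 1.0)


@dataclass
class LoessFit:
    """One fitted LOESS trajectory (span, degree, data, in-sample fit)."""

    span: float
    degree: int
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    sse: float

    def predict(self, x_new: np.ndarray) -> np.ndarray:
        return loess_predict(self.x, self.y, self.span, self.degree, x_new)


@dataclass
class NormativeModel:
    """Per-bin, per-measure FT norms plus the fitted trajectories."""

    bin_edges: np.ndarray
    mu: pd.DataFrame          # bins x measures
    sigma: pd.DataFrame       # bins x measures
    n: np.ndarray             # FT count per bin
    loess: dict[str, LoessFit] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


@dataclass
class WScoreTable:
    """Per-VPT-subject, per-measure deviation scores and bin assignment."""

    w: pd.DataFrame           # subjects x 33, indexed by subject_id
    bin_index: pd.Series      # subject_id -> assigned bin

    def validate(self) -> None:
        if not np.isfinite(self.w.to_numpy()).all():
            raise ValueError("W-score table contains non-finite values")


def loess_predict(
    x: np.ndarray,
    y: np.ndarray,
    span: float,
    degree: int = 2,
    x_new: np.ndarray | None = None,
) -> np.ndarray:
    """LOESS: local weighted polynomial regression with tricube weights.

    For each query point the ceil(span * n) nearest neighbours are weighted by
    w = (1 - (d / d_max)^3)^3 and a degree-``degree`` polynomial is fitted by
    weighted least squares; the prediction is its value at the query point.
    Rank-deficient local systems fall back to the minimum-norm solution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x_new is None:
        x_new = x
    x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
    n = len(x)
    if n < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} points, got {n}")
    k = math.ceil(span * n)
    if k < degree + 1:
        raise ValueError(
            f"span {span} gives {k} neighbours, fewer than degree + 1 = {degree + 1}"
        )
    k = min(k, n)
    out = np.empty(len(x_new))
    for j, x0 in enumerate(x_new):
        d = np.abs(x - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax > 0:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        else:
            w = np.ones(k)
        xc = x[idx] - x0
        design = np.vander(xc, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        out[j] = coef[0]
    return out


def fit_loess(x: np.ndarray, y: np.ndarray, span: float, degree: int = 2) -> LoessFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fitted = loess_predict(x, y, span, degree, x)
    return LoessFit(span=span, degree=degree, x=x, y=y, fitted=fitted,
                    sse=float(np.sum((y - fitted) ** 2)))


def _loocv_sse(x: np.ndarray, y: np.ndarray, span: float, degree: int) -> float:
    n = len(x)
    err = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        pred = loess_predict(x[mask], y[mask], span, degree, np.array([x[i]]))[0]
        err += (y[i] - pred) ** 2
    return err


def optimize_span(
    x: np.ndarray,
    y: np.ndarray,
    degree: int = 2,
    objective: str | callable = "sse",
) -> float:
    """Span in [0.05, 1.0] minimizing the objective by bounded Brent search.

    ``objective`` is "sse" (in-sample sum of squared errors), "loocv"
    (leave-one-out prediction SSE) or any callable span -> value.  When 5% of
    the points cannot support the polynomial degree, the lower search bound is
    raised to the smallest feasible span (logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    lo, hi = SPAN_BOUNDS
    min_feasible = (degree + 1) / n
    if math.ceil(lo * n) < degree + 1:
        lo = min_feasible
        logger.warning("optimize_span: raised lower bound to smallest feasible span %.4f", lo)

    if callable(objective):
        fun = objective
    elif objective == "sse":
        fun = lambda s: fit_loess(x, y, s, degree).sse
    elif objective == "loocv":
        fun = lambda s: _loocv_sse(x, y, s, degree)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    res = minimize_scalar(fun, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4})
    # bounded Brent never evaluates the interval endpoints, yet the in-sample
    # SSE objective often attains its minimum at the smallest feasible span;
    # pick the best of the interior solution and the two endpoints
    candidates = [(float(res.fun), float(res.x))] + [(fun(s), s) for s in (lo, hi)]
    return min(candidates)[1]


def make_age_bins(
    mode: str = "study",
    age_min: float = 72.0,
    age_max: float = 173.0,
    n_bins: int = 4,
) -> np.ndarray:
    """Age-bin edges: the four published study bins, or equal-width bins."""
    if mode == "study":
        return np.array(STUDY_BIN_EDGES)
    if mode == "equal":
        if not age_min < age_max:
            raise ValueError("age_min must be < age_max")
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        return np.linspace(age_min, age_max, n_bins + 1)
    raise ValueError(f"mode must be 'study' or 'equal', got {mode!r}")


def assign_bins(ages: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    """Half-open bins [lo, hi), last bin closed; out-of-range ages snap to the
    nearest bin with a logged warning (never dropped)."""
    ages = np.asarray(ages, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.searchsorted(edges, ages, side="right") - 1
    n_bins = len(edges) - 1
    outside = (ages < edges[0]) | (ages > edges[-1])
    if outside.any():
        logger.warning("assign_bins: %d age(s) outside the bin range assigned to the "
                       "nearest bin", int(outside.sum()))
    idx = np.clip(idx, 0, n_bins - 1)
    return idx


def compute_bin_norms(
    ft_structural: StructuralTable,
    ft_ages: np.ndarray,
    bin_edges: np.ndarray,
) -> NormativeModel:
    """Sample mean and SD (denominator n-1) per age bin and measure, FT only."""
    vals = ft_structural.measures()
    ft_ages = np.asarray(ft_ages, dtype=float)
    if len(ft_ages) != len(vals):
        raise ValueError("ft_ages length does not match the structural table")
    idx = assign_bins(ft_ages, bin_edges)
    n_bins = len(bin_edges) - 1
    mu = np.empty((n_bins, len(STRUCTURAL_COLUMNS)))
    sigma = np.empty_like(mu)
    counts = np.empty(n_bins, dtype=int)
    for b in range(n_bins):
        block = vals.to_numpy(float)[idx == b]
        counts[b] = len(block)
        if counts[b] < 2:
            raise ValueError(
                f"age bin {b} [{bin_edges[b]}, {bin_edges[b + 1]}] has "
                f"{counts[b]} full-term subject(s); need >= 2"
            )
        if counts[b] < 5:
            logger.warning("age bin %d has only %d full-term subjects", b, counts[b])
        mu[b] = block.mean(axis=0)
        sigma[b] = block.std(axis=0, ddof=1)
        zero = np.flatnonzero(sigma[b] == 0)
        if len(zero):
            raise ValueError(
                f"zero normative SD in bin {b} for {STRUCTURAL_COLUMNS[zero[0]]}"
            )
    cols = list(STRUCTURAL_COLUMNS)
    return NormativeModel(
        bin_edges=np.asarray(bin_edges, dtype=float),
        mu=pd.DataFrame(mu, columns=cols),
        sigma=pd.DataFrame(sigma, columns=cols),
        n=counts,
    )


def fit_normative_model(
    ft_structural: StructuralTable,
    ft_ages: np.ndarray,
    bin_edges: np.ndarray | None = None,
    degree: int = 2,
    objective: str = "sse",
) -> NormativeModel:
    """Bin norms plus a span-optimized LOESS trajectory per measure."""
    ft_ages = np.asarray(ft_ages, dtype=float)
    if bin_edges is None:
        bin_edges = make_age_bins("study")
    model = compute_bin_norms(ft_structural, ft_ages, bin_edges)
    vals = ft_structural.measures()
    for col in STRUCTURAL_COLUMNS:
        y = vals[col].to_numpy(float)
        span = optimize_span(ft_ages, y, degree=degree, objective=objective)
        model.loess[col] = fit_loess(ft_ages, y, span, degree)
    return model


def compute_w_scores(
    vpt_structural: StructuralTable,
    vpt_ages: np.ndarray,
    norms: NormativeModel,
    basis: str = "bins",
) -> WScoreTable:
    """W-scores of VPT subjects against FT norms.

    ``basis`` = "bins" uses the age-bin mean/SD; "loess" uses the LOESS
    prediction at the subject's age as the mean and the SD of the FT LOESS
    residuals as the scale.
    """
    vals = vpt_structural.measures()
    vpt_ages = np.asarray(vpt_ages, dtype=float)
    if len(vpt_ages) != len(vals):
        raise ValueError("vpt_ages length does not match the structural table")
    idx = assign_bins(vpt_ages, norms.bin_edges)
    if basis == "bins":
        mu = norms.mu.to_numpy()[idx]
        sigma = norms.sigma.to_numpy()[idx]
    elif basis == "loess":
        if not norms.loess:
            raise ValueError("basis='loess' requires fitted LOESS trajectories")
        mu = np.column_stack(
            [norms.loess[c].predict(vpt_ages) for c in STRUCTURAL_COLUMNS]
        )
        resid_sd = np.array(
            [(norms.loess[c].y - norms.loess[c].fitted).std(ddof=1)
             for c in STRUCTURAL_COLUMNS]
        )
        if (resid_sd <= 1e-12).any():
            bad = STRUCTURAL_COLUMNS[int(np.argmin(resid_sd))]
            raise ValueError(
                f"LOESS residual SD is zero for {bad}; the trajectory "
                "interpolates the data (span too small for a W-score scale)"
            )
        sigma = np.tile(resid_sd, (len(vpt_ages), 1))
    else:
        raise ValueError(f"basis must be 'bins' or 'loess', got {basis!r}")
    w = (vals.to_numpy(float) - mu) / sigma
    table = WScoreTable(
        w=pd.DataFrame(w, index=vals.index, columns=list(STRUCTURAL_COLUMNS)),
        bin_index=pd.Series(idx, index=vals.index, name="bin_index"),
    )
    table.validate()
    return table
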
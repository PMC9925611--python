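"""Partial least squares correlation (PLSC) with permutation and bootstrap.

PLSC relates a clinical block X (n x p) and a structural block Y (n x q) by
a singular value decomposition of their cross-correlation matrix

    R = Xz' Yz / (n - 1) = U S V',

where Xz, Yz are column-wise z-scored (mean 0, SD 1, denominator n - 1).
Each latent component k pairs a clinical salience U[:, k] with a structural
salience V[:, k]; the latent scores Xz U and Yz V have covariance S_k, the
largest achievable for orthonormal weight systems.  Because the SVD produces
orthogonal composites, the method is insensitive to multicollinearity within
either block.

Reported per component:

* singular values and permutation p-values — rows of X are permuted, the
  decomposition recomputed, and the k-th observed singular value compared
  against the null distribution of k-th permuted singular values with the
  add-one convention p = (1 + #{S*_k >= S_k}) / (1 + n_perm);
* loadings (structure coefficients) — the correlation of each original
  column with its block's latent score, bounded in [-1, 1];
* bootstrap stability — subjects resampled with replacement jointly in X and
  Y, saliences sign-aligned to the original fit, loadings recomputed per
  resample; the bootstrap SD yields a z-score (loading / SD) and a two-sided
  normal p-value;
* robustness — a loading is robust when its bootstrap p-value is below alpha
  AND its magnitude reaches the correlation threshold (defaults 0.01 / 0.4).

Sign convention: the largest-magnitude entry of each clinical salience is
made positive, with the matching flip applied to the structural salience, so
repeated fits are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


class ConstantColumnError(ValueError):
    """A column has zero variance and cannot be z-scored."""


def _zscore(A: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    sd = A.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        label = names[bad[0]] if names else f"column {bad[0]}"
        raise ConstantColumnError(f"constant column: {label}")
    return (A - A.mean(axis=0)) / sd


def _cross_correlation(X: np.ndarray, Y: np.ndarray,
                       x_names=None, y_names=None) -> np.ndarray:
    n = len(X)
    Xz = _zscore(X, x_names)
    Yz = _zscore(Y, y_names)
    return Xz.T @ Yz / (n - 1)


def _column_correlations(block: np.ndarray, latent: np.ndarray) -> np.ndarray:
    """Correlation of each original column with each latent score (p x K)."""
    bz = block - block.mean(axis=0)
    lz = latent - latent.mean(axis=0)
    bn = np.linalg.norm(bz, axis=0)
    ln = np.linalg.norm(lz, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (bz.T @ lz) / np.outer(bn, ln)
    return np.clip(out, -1.0, 1.0)


@dataclass
class PLSCResult:
    """Decomposition, inference and stability output of one PLSC run."""

    singular_values: np.ndarray
    saliences_X: np.ndarray
    saliences_Y: np.ndarray
    latent_X: np.ndarray
    latent_Y: np.ndarray
    loadings_X: np.ndarray
    loadings_Y: np.ndarray
    x_names: list[str]
    y_names: list[str]
    perm_p: np.ndarray | None = None
    boot_sd_X: np.ndarray | None = None
    boot_sd_Y: np.ndarray | None = None
    boot_z_X: np.ndarray | None = None
    boot_z_Y: np.ndarray | None = None
    boot_p_X: np.ndarray | None = None
    boot_p_Y: np.ndarray | None = None
    robust_X: np.ndarray | None = None
    robust_Y: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.singular_values)


def plsc_fit(
    X: np.ndarray,
    Y: np.ndarray,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> PLSCResult:
    """SVD of the cross-correlation matrix of z-scored X and Y."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = len(X)
    if n != len(Y):
        raise ValueError("X and Y must have the same number of rows")
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    x_names = list(x_names) if x_names else [f"x{i}" for i in range(X.shape[1])]
    y_names = list(y_names) if y_names else [f"y{i}" for i in range(Y.shape[1])]
    Xz = _zscore(X, x_names)
    Yz = _zscore(Y, y_names)
    R = Xz.T @ Yz / (n - 1)
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    # deterministic orientation: dominant clinical salience entry positive
    for k in range(len(S)):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1
    latent_X = Xz @ U
    latent_Y = Yz @ V
    return PLSCResult(
        singular_values=S,
        saliences_X=U,
        saliences_Y=V,
        latent_X=latent_X,
        latent_Y=latent_Y,
        loadings_X=_column_correlations(X, latent_X),
        loadings_Y=_column_correlations(Y, latent_Y),
        x_names=x_names,
        y_names=y_names,
    )


def _singular_values(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return np.linalg.svd(_cross_correlation(X, Y), compute_uv=False)


def permutation_pvalues(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    permutations: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Permutation p-values for each singular value.

    Rows of X are permuted (Y fixed) and the decomposition recomputed; the
    k-th observed singular value is compared per-rank to the permuted ones.
    ``permutations`` overrides the random draws (mainly a test seam).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    s_obs = _singular_values(X, Y)
    if permutations is None:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        permutations = [rng.permutation(len(X)) for _ in range(n_perm)]
    count = np.zeros_like(s_obs)
    for perm in permutations:
        s_perm = _singular_values(X[perm], Y)
        count += s_perm >= s_obs
    return (1.0 + count) / (1.0 + len(permutations))


def bootstrap_loadings(
    X: np.ndarray,
    Y: np.ndarray,
    n_boot: int = 500,
    seed: int | None = None,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> dict[str, np.ndarray]:
    """Bootstrap SDs, z-scores and p-values for the loadings.

    Subjects are resampled with replacement jointly in X and Y; each
    resample's saliences are sign-aligned to the original fit (per-component
    dot-product flip on the clinical side, mirrored on the structural side)
    and loadings recomputed on the resampled data.  A resample producing a
    constant column is redrawn (at most 10 retries, logged).  Zero bootstrap
    SD yields an infinite z with p = 0.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    base = plsc_fit(X, Y, x_names, y_names)
    n = len(X)
    acc_X = np.empty((n_boot,) + base.loadings_X.shape)
    acc_Y = np.empty((n_boot,) + base.loadings_Y.shape)
    for b in range(n_boot):
        for attempt in range(11):
            idx = rng.integers(0, n, size=n)
            try:
                fit_b = plsc_fit(X[idx], Y[idx], base.x_names, base.y_names)
                break
            except ConstantColumnError:
                if attempt == 10:
                    raise
                logger.warning("bootstrap resample %d redrawn (constant column)", b)
        flips = np.sign(np.sum(fit_b.saliences_X * base.saliences_X, axis=0))
        flips[flips == 0] = 1.0
        acc_X[b] = fit_b.loadings_X * flips
        acc_Y[b] = fit_b.loadings_Y * flips
    sd_X = acc_X.std(axis=0, ddof=1)
    sd_Y = acc_Y.std(axis=0, ddof=1)
    # SDs at float rounding level mean the loading is invariant under
    # resampling (perfect association): report the infinite-z sentinel
    tiny = 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        z_X = np.where(sd_X > tiny, base.loadings_X / np.where(sd_X > tiny, sd_X, 1.0),
                       np.sign(base.loadings_X) * np.inf)
        z_Y = np.where(sd_Y > tiny, base.loadings_Y / np.where(sd_Y > tiny, sd_Y, 1.0),
                       np.sign(base.loadings_Y) * np.inf)
    p_X = 2.0 * stats.norm.sf(np.abs(z_X))
    p_Y = 2.0 * stats.norm.sf(np.abs(z_Y))
    return {
        "boot_sd_X": sd_X, "boot_sd_Y": sd_Y,
        "boot_z_X": z_X, "boot_z_Y": z_Y,
        "boot_p_X": p_X, "boot_p_Y": p_Y,
        "boot_mean_X": acc_X.mean(axis=0), "boot_mean_Y": acc_Y.mean(axis=0),
    }


def robust_mask(
    loadings: np.ndarray,
    boot_p: np.ndarray,
    alpha: float = 0.01,
    r_threshold: float = 0.4,
) -> dict[str, np.ndarray]:
    """Robustness: bootstrap p below alpha AND |loading| at the threshold.

    Returns the combined mask plus each criterion separately.
    """
    loadings = np.asarray(loadings)
    boot_p = np.asarray(boot_p)
    if loadings.shape != boot_p.shape:
        raise ValueError("loadings and boot_p shapes differ")
    stable = boot_p < alpha
    strong = np.abs(loadings) >= r_threshold
    return {"robust": stable & strong, "stable": stable, "strong": strong}


def run_plsc(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 1000,
    n_boot: int = 500,
    seed: int | None = None,
    alpha: float = 0.01,
    r_threshold: float = 0.4,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> PLSCResult:
    """Full PLSC: decomposition, permutation test, bootstrap, robustness."""
    result = plsc_fit(X, Y, x_names, y_names)
    rng = np.random.default_rng(seed)
    perm_seed, boot_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    result.perm_p = permutation_pvalues(X, Y, n_perm=n_perm, seed=perm_seed)
    boot = bootstrap_loadings(X, Y, n_boot=n_boot, seed=boot_seed,
                              x_names=x_names, y_names=y_names)
    result.boot_sd_X = boot["boot_sd_X"]
    result.boot_sd_Y = boot["boot_sd_Y"]
    result.boot_z_X = boot["boot_z_X"]
    result.boot_z_Y = boot["boot_z_Y"]
    result.boot_p_X = boot["boot_p_X"]
    result.boot_p_Y = boot["boot_p_Y"]
    result.robust_X = robust_mask(result.loadings_X, result.boot_p_X,
                                  alpha, r_threshold)["robust"]
    result.robust_Y = robust_mask(result.loadings_Y, result.boot_p_Y,
                                  alpha, r_threshold)["robust"]
    result.extras.update(
        {"perm_seed": perm_seed, "boot_seed": boot_seed,
         "boot_mean_X": boot["boot_mean_X"], "boot_mean_Y": boot["boot_mean_Y"],
         "n_perm": n_perm, "n_boot": n_boot,
         "alpha": alpha, "r_threshold": r_threshold}
    )
    return result
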
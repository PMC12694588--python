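"""Behavioral partial least squares (PLS) for voxelwise SD_BOLD.

The predictor block (age and/or log-HRV measures) and the voxel block
(per-subject SD_BOLD values) are z-scored across subjects; the p x v
matrix of Pearson correlations between each predictor and each voxel is
decomposed by SVD:

    R = U S V^T

Each latent variable (LV) pairs a predictor-salience vector (column of
U), a unit-length voxel-salience pattern (column of V) and a singular
value whose square, normalized by the total, is the fraction of the
cross-block covariance the LV explains.  A subject's brain score is the
dot product of their z-scored voxel data with the LV's voxel saliences.

Inference is by resampling: permutation of subject rows of the
predictor block tests LV singular values (rank-matched, add-one p), and
subject-level bootstrap resampling yields per-voxel bootstrap ratios
(mean bootstrap salience / bootstrap SE); |BSR| > 2.70 approximates a
99% confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PlsModel",
    "PermutationResult",
    "BootstrapResult",
    "SlopeFit",
    "zscore_columns",
    "fit_pls",
    "behavioral_pls",
    "permutation_test",
    "bootstrap_test",
    "slope_vs_brainscores",
    "effect_direction_map",
    "lv_summary_table",
]

logger = logging.getLogger(__name__)

BSR_THRESHOLD = 2.70


def zscore_columns(M: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Z-score each column across rows (mean 0, SD 1, divisor n-1).

    Raises on zero-variance columns, naming the offender.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    sd = M.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        label = names[bad[0]] if names else f"column {bad[0]}"
        raise ValueError(f"zero-variance column cannot be z-scored: {label}")
    return (M - M.mean(axis=0)) / sd


@dataclass
class PlsModel:
    """Fitted behavioral PLS decomposition."""

    predictor_names: list[str]
    X: np.ndarray              # n x p, z-scored predictors
    Yz: np.ndarray             # n x v, z-scored voxel values
    R: np.ndarray              # p x v cross-correlation matrix
    singular_values: np.ndarray      # k, descending
    predictor_saliences: np.ndarray  # p x k
    voxel_saliences: np.ndarray      # v x k, unit-length columns
    brain_scores: np.ndarray         # n x k
    cov_explained: np.ndarray        # k, sums to 1

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.Yz.shape[1]

    def pct_negative_voxel_weights(self, lv: int = 0) -> float:
        """Percentage of voxels with negative salience on one LV."""
        sal = self.voxel_saliences[:, lv]
        return 100.0 * float(np.mean(sal < 0))


def _svd_correlations(X: np.ndarray, Yz: np.ndarray):
    n = X.shape[0]
    R = X.T @ Yz / (n - 1)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    return R, U, s, Vt.T


def _apply_sign_convention(U: np.ndarray, V: np.ndarray) -> None:
    """Scale each LV so its largest-|.| predictor salience is positive.

    SVD signs are arbitrary per component; fixing them makes outputs
    reproducible across platforms.  Operates in place.
    """
    for k in range(U.shape[1]):
        lead = np.argmax(np.abs(U[:, k]))
        if U[lead, k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1


def fit_pls(
    X: np.ndarray,
    Yz: np.ndarray,
    predictor_names: list[str] | None = None,
) -> PlsModel:
    """Fit behavioral PLS from z-scored predictor and voxel blocks."""
    X = np.asarray(X, dtype=float)
    Yz = np.asarray(Yz, dtype=float)
    n, p = X.shape
    v = Yz.shape[1]
    if Yz.shape[0] != n:
        raise ValueError("X and Yz must have the same number of subjects")
    if n < 3:
        raise ValueError(f"PLS requires >= 3 subjects, got {n}")
    if v < p:
        raise ValueError(f"need at least as many voxels ({v}) as predictors ({p})")
    if predictor_names is None:
        predictor_names = [f"x{i}" for i in range(p)]
    if np.linalg.matrix_rank(X) < p:
        logger.warning("predictor block is rank-deficient; SVD proceeds")
    R, U, s, V = _svd_correlations(X, Yz)
    _apply_sign_convention(U, V)
    total = float(np.sum(s**2))
    cov_explained = s**2 / total if total > 0 else np.full_like(s, np.nan)
    return PlsModel(
        predictor_names=list(predictor_names),
        X=X,
        Yz=Yz,
        R=R,
        singular_values=s,
        predictor_saliences=U,
        voxel_saliences=V,
        brain_scores=Yz @ V,
        cov_explained=cov_explained,
    )


def behavioral_pls(
    predictors: pd.DataFrame,
    Y: np.ndarray,
) -> PlsModel:
    """Convenience wrapper: z-scores both blocks, then fits.

    ``predictors`` holds one column per predictor on its raw scale;
    ``Y`` is the raw subject x voxel SD_BOLD matrix in the same row
    order.
    """
    names = list(predictors.columns)
    X = zscore_columns(predictors.to_numpy(float), names)
    Yz = zscore_columns(np.asarray(Y, dtype=float))
    return fit_pls(X, Yz, names)


@dataclass
class PermutationResult:
    """Permutation null for LV singular values."""

    n_perm: int
    p_values: np.ndarray                 # per LV
    permuted_singular_values: np.ndarray  # n_perm x k
    seed: int


def permutation_test(
    model: PlsModel, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Permute subject rows of X (Y fixed), refit, compare singular values.

    Comparison is rank-matched (permuted s_i against observed s_i for
    each LV index i); p = (# permuted >= observed + 1) / (n_perm + 1).
    Row permutation of z-scored columns leaves them z-scored, so no
    re-standardization is needed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = model.n_subjects
    k = len(model.singular_values)
    perm_s = np.empty((n_perm, k))
    for i in range(n_perm):
        perm = rng.permutation(n)
        Rp = model.X[perm].T @ model.Yz / (n - 1)
        perm_s[i] = np.linalg.svd(Rp, compute_uv=False)[:k]
    exceed = (perm_s >= model.singular_values[None, :]).sum(axis=0)
    p = (exceed + 1) / (n_perm + 1)
    return PermutationResult(
        n_perm=n_perm, p_values=p, permuted_singular_values=perm_s, seed=seed
    )


@dataclass
class BootstrapResult:
    """Per-voxel bootstrap-ratio reliability for each LV."""

    n_boot: int
    mean_salience: np.ndarray   # v x k
    salience_se: np.ndarray     # v x k
    bootstrap_ratio: np.ndarray  # v x k (NaN where SE == 0)
    significant: np.ndarray     # v x k bool
    threshold: float
    seed: int
    n_redrawn: int = 0

    def pct_passing(self, lv: int = 0) -> float:
        return 100.0 * float(np.mean(self.significant[:, lv]))


def bootstrap_test(
    model: PlsModel,
    n_boot: int = 1000,
    threshold: float = BSR_THRESHOLD,
    seed: int = 0,
    max_redraws: int = 1000,
) -> BootstrapResult:
    """Bootstrap subjects with replacement; BSR = mean salience / SE.

    Each replicate resamples subjects jointly in X and Yz,
    re-standardizes within the replicate so R stays a correlation
    matrix, refits the SVD, and sign-aligns each voxel-salience column
    to the original fit (sign of the dot product).  Replicates with a
    zero-variance predictor column are redrawn and counted.  Voxels with
    zero bootstrap SE are flagged non-significant (ratio undefined).
    """
    if model.n_subjects < 3:
        raise ValueError("bootstrap requires >= 3 subjects")
    rng = np.random.default_rng(seed)
    n, v = model.n_subjects, model.n_voxels
    k = len(model.singular_values)
    sums = np.zeros((v, k))
    sumsq = np.zeros((v, k))
    redrawn = 0
    done = 0
    while done < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb = model.X[idx]
        Yb = model.Yz[idx]
        sdx = Xb.std(axis=0, ddof=1)
        sdy = Yb.std(axis=0, ddof=1)
        if np.any(sdx == 0) or np.any(sdy == 0):
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        Xb = (Xb - Xb.mean(axis=0)) / sdx
        Yb = (Yb - Yb.mean(axis=0)) / sdy
        Rb = Xb.T @ Yb / (n - 1)
        _, sb, Vbt = np.linalg.svd(Rb, full_matrices=False)
        Vb = Vbt.T[:, :k]
        # sign-align each replicate LV to the original voxel saliences
        signs = np.sign(np.einsum("vk,vk->k", Vb, model.voxel_saliences))
        signs[signs == 0] = 1.0
        Vb = Vb * signs
        sums += Vb
        sumsq += Vb**2
        done += 1
    mean = sums / n_boot
    var = (sumsq - n_boot * mean**2) / (n_boot - 1)
    se = np.sqrt(np.clip(var, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, mean / se, np.nan)
    sig = np.abs(np.nan_to_num(bsr, nan=0.0)) > threshold
    if redrawn:
        logger.info("bootstrap_test: %d degenerate replicates redrawn", redrawn)
    n_zero_se = int(np.sum(se == 0))
    if n_zero_se:
        logger.info(
            "bootstrap_test: %d voxel/LV cells with zero SE flagged "
            "non-significant", n_zero_se,
        )
    return BootstrapResult(
        n_boot=n_boot,
        mean_salience=mean,
        salience_se=se,
        bootstrap_ratio=bsr,
        significant=sig,
        threshold=threshold,
        seed=seed,
        n_redrawn=redrawn,
    )


@dataclass
class SlopeFit:
    """OLS slope of brain scores on an (unstandardized) predictor."""

    predictor: str
    beta: float
    se: float
    t: float
    p: float
    n: int


def slope_vs_brainscores(
    predictor_values: np.ndarray,
    brain_scores: np.ndarray,
    predictor_name: str = "predictor",
) -> SlopeFit:
    """OLS of brain scores on one raw predictor, with intercept."""
    x = np.asarray(predictor_values, dtype=float)
    y = np.asarray(brain_scores, dtype=float)
    if len(x) != len(y):
        raise ValueError("predictor and brain scores must align")
    if len(x) < 3:
        raise ValueError("need >= 3 subjects")
    if x.std(ddof=1) == 0:
        raise ValueError(f"zero-variance predictor {predictor_name!r}")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return SlopeFit(
        predictor=predictor_name,
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        t=float(res.tvalues[1]),
        p=float(res.pvalues[1]),
        n=len(x),
    )


def effect_direction_map(
    voxel_saliences_lv: np.ndarray, slope_sign: float
) -> np.ndarray:
    """Per-voxel signed direction of a predictor's association.

    direction = sign(salience) x sign(beta); +1 means the predictor is
    associated with increased SD_BOLD at that voxel (e.g. negative
    saliences combined with a negative predictor-vs-brain-score slope).
    Zero saliences map to 0.
    """
    return np.sign(voxel_saliences_lv) * np.sign(slope_sign)


def lv_summary_table(
    model: PlsModel,
    perm: PermutationResult,
    boot: BootstrapResult,
    raw_predictors: pd.DataFrame,
    lvs: tuple[int, ...] = (0,),
    model_name: str = "model",
) -> pd.DataFrame:
    """Per-LV, per-predictor summary mirroring the standard PLS report:

    % negative voxel weights, slope of brain scores on each raw
    predictor (beta, SE, t, p), LV permutation p, covariance explained,
    and % voxels passing the bootstrap-ratio threshold.
    """
    rows = []
    for lv in lvs:
        for name in model.predictor_names:
            fit = slope_vs_brainscores(
                raw_predictors[name].to_numpy(float),
                model.brain_scores[:, lv],
                name,
            )
            rows.append(
                {
                    "model": model_name,
                    "lv": lv + 1,
                    "predictor": name,
                    "pct_negative_voxel_weights": model.pct_negative_voxel_weights(lv),
                    "beta_vs_brain_scores": fit.beta,
                    "se": fit.se,
                    "t": fit.t,
                    "p": fit.p,
                    "permutation_p": float(perm.p_values[lv]),
                    "cov_explained": float(model.cov_explained[lv]),
                    "pct_voxels_passing_bsr": boot.pct_passing(lv),
                }
            )
    return pd.DataFrame(rows)
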
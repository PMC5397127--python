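"""Voxelwise group statistics: GLM, cluster inference, FDR, scalar tests.

The second-level model is an ordinary-least-squares GLM fit independently
at every voxel, with a group indicator and nuisance covariates (age, total
intracranial volume, depression and trait-anxiety scores).  Cluster-extent
inference follows the standard two-step recipe: a cluster-forming threshold
of p < 0.001 at the voxel level (directional t, control > patient by
default), connected components under 18-neighbour connectivity, and a
cluster-level p-value for each cluster's extent from the permutation
distribution of the maximum cluster size (Freedman-Lane scheme: residuals
of the reduced model are permuted, so nuisance effects are respected).
Benjamini-Hochberg FDR is then applied across the surviving clusters.

Scalar helpers reconstruct two-group one-way ANOVA F statistics from
printed summary statistics and compute Spearman rank correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .phantom import SubjectRecord

__all__ = [
    "GLMDesign",
    "StatMap",
    "design_from_records",
    "glm_fit",
    "cluster_threshold",
    "permutation_cluster_pvalues",
    "fdr_adjust",
    "interaction_analysis",
    "anova_from_summary",
    "spearman_rho",
    "connectivity_structure",
]

DEFAULT_COVARIATES = ("age", "tiv", "bdi", "stai")


@dataclass
class GLMDesign:
    """Design matrix with named regressors and a contrast of interest."""

    matrix: np.ndarray  # subjects x regressors
    names: list[str]
    contrast: np.ndarray  # one row per contrast dimension is not supported; 1D

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        n, p = self.matrix.shape
        if len(self.names) != p:
            raise ValueError("one name per design column required")
        if self.contrast.shape != (p,):
            raise ValueError("contrast must be conformable with the design")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < p:
            collinear = _collinear_columns(self.matrix, self.names)
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {p}); "
                f"collinear columns: {collinear}"
            )

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def df_resid(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns that do not add rank, scanning left to right."""
    bad = []
    kept: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


def design_from_records(
    records: list[SubjectRecord],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    effect: str = "group",
    direction: str = "control_gt_patient",
) -> GLMDesign:
    """Build a second-level design from subject records.

    ``effect='group'`` yields an intercept + patient indicator + centred
    covariates, with the contrast picking the group effect (positive t
    means control > patient under the default direction).
    ``effect='med_months'`` builds the medication regression: months on
    medication as the variable of interest with the same nuisance set.
    """
    n = len(records)
    cols = [np.ones(n)]
    names = ["intercept"]
    if effect == "group":
        groups = np.array([1.0 if r.group == "patient" else 0.0 for r in records])
        if len(np.unique(groups)) != 2:
            raise ValueError("group effect requires both groups present")
        cols.append(groups)
        names.append("group_patient")
    elif effect == "med_months":
        med = np.array([float(r.med_months) for r in records])
        cols.append(med - med.mean())
        names.append("med_months")
    else:
        raise ValueError(f"unknown effect {effect!r}")
    for cov in covariates:
        v = np.array([float(getattr(r, cov)) for r in records])
        cols.append(v - v.mean())
        names.append(cov)
    x = np.column_stack(cols)
    contrast = np.zeros(x.shape[1])
    if effect == "group":
        contrast[names.index("group_patient")] = (
            -1.0 if direction == "control_gt_patient" else 1.0
        )
    else:
        contrast[names.index("med_months")] = 1.0
    return GLMDesign(matrix=x, names=names, contrast=contrast)


@dataclass
class StatMap:
    """Voxelwise statistic values with degrees of freedom and p-values."""

    values: np.ndarray  # t or F per voxel (flat, over mask)
    p: np.ndarray
    df: tuple[float, ...]
    kind: str  # "t" | "F"
    saturated: np.ndarray | None = None  # zero-residual voxels, if any


def _ols_t(
    y: np.ndarray, x: np.ndarray, contrast: np.ndarray, two_sided: bool
) -> StatMap:
    """Vectorized per-voxel OLS t statistics.  y: voxels x subjects."""
    n, p = x.shape
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T  # voxels x p
    resid = y - beta @ x.T
    rss = np.einsum("vn,vn->v", resid, resid)
    sigma2 = rss / df
    cvar = float(contrast @ pinv @ pinv.T @ contrast)
    se = np.sqrt(sigma2 * cvar)
    eff = beta @ contrast
    # Zero residual variance up to round-off counts as saturated.
    msy = np.einsum("vn,vn->v", y, y) / n
    saturated = rss <= 1e-24 * n * (msy + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = eff / se
    # Zero residual variance: a nonzero effect saturates to +/-inf
    # (p -> 0 in its direction); no effect and no variance is t = 0.
    with np.errstate(invalid="ignore"):
        t = np.where(saturated & (eff != 0), np.sign(eff) * np.inf, t)
        t = np.where(saturated & (eff == 0), 0.0, t)
    if two_sided:
        pvals = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        pvals = stats.t.sf(t, df)
    pvals = np.where(saturated & (eff == 0), 1.0, pvals)
    return StatMap(values=t, p=pvals, df=(float(df),), kind="t", saturated=saturated)


def _ols_f(y: np.ndarray, x: np.ndarray, cmat: np.ndarray) -> StatMap:
    """F test of a contrast matrix (rows are contrasts)."""
    n, p = x.shape
    df2 = n - p
    q = cmat.shape[0]
    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T
    resid = y - beta @ x.T
    rss = np.einsum("vn,vn->v", resid, resid)
    sigma2 = rss / df2
    cb = beta @ cmat.T  # voxels x q
    m = cmat @ pinv @ pinv.T @ cmat.T  # q x q
    m_inv = np.linalg.inv(m)
    quad = np.einsum("vq,qr,vr->v", cb, m_inv, cb)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = quad / (q * sigma2)
    zero = sigma2 == 0
    f = np.where(zero, np.where(quad > 0, np.inf, 0.0), f)
    pvals = stats.f.sf(f, q, df2)
    pvals = np.where(zero & (quad > 0), 0.0, pvals)
    return StatMap(values=f, p=pvals, df=(float(q), float(df2)), kind="F", saturated=zero)


def glm_fit(
    y: np.ndarray,
    design: GLMDesign,
    contrast: np.ndarray | None = None,
    kind: str = "t",
    two_sided: bool = False,
) -> StatMap:
    """Ordinary least squares per voxel with a t or F contrast.

    ``y`` is voxels x subjects (masked voxels only; a 1D array is treated
    as a single voxel).  The default operating mode is a directional t for
    the design's contrast (one-sided p), matching the reporting convention
    of decreases in patients; ``two_sided=True`` gives the symmetric test
    and ``kind='F'`` the F mode.  Voxels with zero residual variance are
    flagged saturated, with p = 0 for a nonzero effect.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[1] != design.n_subjects:
        raise ValueError("y must have one column per subject")
    c = design.contrast if contrast is None else np.asarray(contrast, dtype=float)
    if kind == "t":
        if c.ndim != 1:
            raise ValueError("t mode takes a 1D contrast")
        return _ols_t(y, design.matrix, c, two_sided)
    if kind == "F":
        cmat = np.atleast_2d(c)
        return _ols_f(y, design.matrix, cmat)
    raise ValueError(f"unknown kind {kind!r}")


def connectivity_structure(connectivity: int = 18) -> np.ndarray:
    """3D neighbourhood footprint: 6, 18 (default convention) or 26."""
    rank = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if rank is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank)


def cluster_threshold(
    p_map: np.ndarray,
    stat_map: np.ndarray | None = None,
    p_form: float = 0.001,
    connectivity: int = 18,
) -> pd.DataFrame:
    """Form clusters from a voxelwise p map at the cluster-forming threshold.

    Voxels with p < ``p_form`` are grouped into connected components under
    the requested connectivity (18 by default).  Returns one row per
    cluster with the peak voxel index (ties broken by lowest linear index),
    peak statistic and extent in voxels; an empty table if nothing
    survives.
    """
    p_map = np.asarray(p_map, dtype=float)
    if p_map.ndim != 3:
        raise ValueError("p_map must be 3D")
    supra = p_map < p_form
    rows = []
    if supra.any():
        lab, n_clu = ndimage.label(supra, structure=connectivity_structure(connectivity))
        stat = None if stat_map is None else np.asarray(stat_map, dtype=float)
        for cid in range(1, n_clu + 1):
            m = lab == cid
            k = int(m.sum())
            if stat is not None:
                vals = np.where(m, stat, -np.inf)
                peak_flat = int(np.argmax(vals))  # argmax takes the first max
                peak_stat = float(vals.flat[peak_flat])
            else:
                vals = np.where(m, -p_map, -np.inf)
                peak_flat = int(np.argmax(vals))
                peak_stat = float(-vals.flat[peak_flat])
            peak_idx = np.unravel_index(peak_flat, p_map.shape)
            rows.append(
                {
                    "cluster_id": cid,
                    "peak_i": peak_idx[0],
                    "peak_j": peak_idx[1],
                    "peak_k": peak_idx[2],
                    "peak_stat": peak_stat,
                    "extent": k,
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster_id", "peak_i", "peak_j", "peak_k", "peak_stat", "extent"]
    )


def _t_maps_for_perms(
    y: np.ndarray, x: np.ndarray, contrast: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Precompute the pieces of the vectorized t statistic."""
    n, p = x.shape
    df = n - p
    pinv = np.linalg.pinv(x)
    cvar = float(contrast @ pinv @ pinv.T @ contrast)
    hat = x @ pinv  # n x n projection
    return pinv, hat, cvar, df


def _t_stat(y, x, pinv, hat, cvar, df, contrast):
    beta = y @ pinv.T
    resid = y - y @ hat.T
    rss = np.einsum("vn,vn->v", resid, resid)
    se = np.sqrt(np.maximum(rss / df, 0.0) * cvar)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (beta @ contrast) / se
    return np.where(se == 0, 0.0, t)


def permutation_cluster_pvalues(
    y: np.ndarray,
    design: GLMDesign,
    mask: np.ndarray,
    p_form: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 18,
    q_fdr: float = 0.05,
) -> pd.DataFrame:
    """Cluster-extent inference via Freedman-Lane permutation.

    ``y`` is voxels x subjects over ``mask`` (a 3D boolean array giving
    the voxel positions).  The observed directional t map is thresholded at
    voxel p < ``p_form``; each observed cluster's extent k is referred to
    the permutation distribution of the maximum cluster extent:

        p_cluster = (1 + #{perms with max extent >= k}) / (1 + n_perm)

    Permutations follow the Freedman-Lane scheme: the reduced model
    (design without the contrasted columns) is fit once, and its residuals
    are permuted over subjects before adding back the reduced-model fit.
    Cluster-level FDR (Benjamini-Hochberg) is applied across the observed
    clusters.  Reproducible given the seed.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 cannot resolve any useful p-value")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value", stacklevel=2)
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if y.shape[0] != int(mask.sum()):
        raise ValueError("y must have one row per mask voxel")

    x = design.matrix
    contrast = design.contrast
    n = x.shape[0]
    pinv, hat, cvar, df = _t_maps_for_perms(y, x, contrast)
    t_thresh = stats.t.isf(p_form, df)

    t_obs = _t_stat(y, x, pinv, hat, cvar, df, contrast)
    t_vol = np.zeros(mask.shape)
    t_vol[mask] = t_obs
    p_vol = np.ones(mask.shape)
    p_vol[mask] = stats.t.sf(t_obs, df)
    table = cluster_threshold(p_vol, t_vol, p_form=p_form, connectivity=connectivity)
    labels_obs, _ = ndimage.label(
        p_vol < p_form, structure=connectivity_structure(connectivity)
    )

    # Freedman-Lane: residualize on the reduced (nuisance-only) model.
    keep = contrast == 0
    x0 = x[:, keep]
    if x0.shape[1] == 0:
        fitted0 = np.zeros_like(y)
    else:
        pinv0 = np.linalg.pinv(x0)
        fitted0 = (y @ pinv0.T) @ x0.T
    resid0 = y - fitted0

    rng = np.random.default_rng(seed)
    structure = connectivity_structure(connectivity)
    max_extents = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        perm = rng.permutation(n)
        y_star = fitted0 + resid0[:, perm]
        t_star = _t_stat(y_star, x, pinv, hat, cvar, df, contrast)
        supra = np.zeros(mask.shape, dtype=bool)
        supra[mask] = t_star > t_thresh
        if supra.any():
            lab, n_clu = ndimage.label(supra, structure=structure)
            max_extents[b] = np.bincount(lab.ravel())[1:].max() if n_clu else 0
        else:
            max_extents[b] = 0

    if len(table):
        k_obs = table["extent"].to_numpy()
        exceed = (max_extents[None, :] >= k_obs[:, None]).sum(axis=1)
        p_unc = (1.0 + exceed) / (1.0 + n_perm)
        table = table.assign(p_unc=p_unc, p_fdr=fdr_adjust(p_unc))
    else:
        table = table.assign(p_unc=pd.Series(dtype=float), p_fdr=pd.Series(dtype=float))
    table.attrs["cluster_labels"] = labels_obs
    table.attrs["df"] = df
    table.attrs["t_threshold"] = float(t_thresh)
    table.attrs["n_perm"] = n_perm
    table.attrs["q_fdr"] = q_fdr
    return table


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def interaction_analysis(
    y_mt: np.ndarray,
    y_t1: np.ndarray,
    design: GLMDesign,
    **perm_kwargs,
) -> pd.DataFrame | StatMap:
    """Modality x diagnosis interaction via difference images.

    With one observation per subject per modality, the mixed-model
    interaction contrast [control MT > patient MT] > [control T1 > patient
    T1] is algebraically a group contrast on per-subject difference images
    (MT - T1), which is what this computes.  Pass ``mask=...`` (plus
    optional permutation options) to get a cluster table; without a mask a
    voxelwise :class:`StatMap` is returned.
    """
    y_mt = np.atleast_2d(np.asarray(y_mt, dtype=float))
    y_t1 = np.atleast_2d(np.asarray(y_t1, dtype=float))
    if y_mt.shape != y_t1.shape:
        raise ValueError("modalities must cover identical subject sets and voxels")
    d = y_mt - y_t1
    if "mask" in perm_kwargs:
        return permutation_cluster_pvalues(d, design, **perm_kwargs)
    return glm_fit(d, design)


def anova_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, int, float]:
    """Two-group one-way ANOVA reconstructed from printed summaries.

    F = SSB / MSW with SSB = sum n_i (xbar_i - xbar)^2 and
    MSW = sum (n_i - 1) s_i^2 / (N - 2).  Equals the one-way ANOVA on any
    raw dataset realizing those summary statistics.  Returns
    (F, df1, df2, p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    n = n1 + n2
    grand = (n1 * mean1 + n2 * mean2) / n
    ssb = n1 * (mean1 - grand) ** 2 + n2 * (mean2 - grand) ** 2
    msw = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n - 2)
    if msw == 0:
        f = 0.0 if ssb == 0 else np.inf
    else:
        f = ssb / msw
    p = float(stats.f.sf(f, 1, n - 2)) if np.isfinite(f) else 0.0
    return float(f), 1, n - 2, p


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value uses the t approximation.  Requires n >= 4.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
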
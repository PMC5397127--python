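"""Voxelwise quantitative map estimation from multi-echo FLASH contrasts.

The estimation chain is:

1. ``fit_r2star`` — log-linear fit ln S(t) = ln S0 - t*R2* across echoes
   (ordinary least squares of log-signal on echo time).
2. ``extrapolate_te0`` — the TE=0 amplitude exp(ln S0) of each contrast,
   obtained from the same log-linear fit so that the R2* decay is removed
   rather than averaged in.
3. ``estimate_a_r1`` — closed-form amplitude A and longitudinal rate R1
   from the dual-flip-angle PDw/T1w pair under the rational small-angle
   spoiled gradient-echo model S = A*alpha*R1*TR / (R1*TR + alpha^2/2).
4. ``compute_mtsat`` — MT saturation per TR,
   delta = (A*alpha/S_MT - 1)*R1*TR - alpha^2/2,
   evaluated with the MT-weighted protocol's alpha and TR.

Because the TE=0 amplitudes are R2*-free, the estimated delta is invariant
to iron-driven R2* changes — the property that makes MT-saturation maps
retain subcortical contrast where T1-weighted images lose it.

Voxels where a fit is impossible or lands outside the physical range are
masked invalid, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import AcquisitionProtocol, MultiEchoVolume

__all__ = [
    "QuantitativeMaps",
    "R2StarFit",
    "fit_r2star",
    "extrapolate_te0",
    "estimate_a_r1",
    "compute_mtsat",
    "fit_quantitative_maps",
]


@dataclass
class R2StarFit:
    """Result of the voxelwise log-linear decay fit."""

    r2star: np.ndarray  # 1/s, clamped at 0
    ln_s0: np.ndarray  # dimensionless log-amplitude at TE=0
    valid_mask: np.ndarray  # bool: >= 3 usable echoes
    clamped_mask: np.ndarray  # bool: negative fitted slope clamped to 0


@dataclass
class QuantitativeMaps:
    """Voxelwise A, R1, MT saturation and R2* maps on one grid."""

    a: np.ndarray
    r1: np.ndarray
    mtsat: np.ndarray
    r2star: np.ndarray
    ln_s0: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.a, self.r1, self.mtsat, self.r2star, self.ln_s0, self.valid_mask)}
        if len(shapes) != 1:
            raise ValueError("all maps must share one grid")


def _masked_ols_decay(
    data: np.ndarray, echo_times: np.ndarray, min_echoes: int = 3
) -> R2StarFit:
    """OLS of ln(signal) on echo time with per-voxel echo filtering.

    Echoes with non-positive signal are dropped voxelwise; voxels with
    fewer than ``min_echoes`` usable echoes are excluded from the valid
    mask rather than raising.
    """
    te = np.asarray(echo_times, dtype=float)
    usable = data > 0
    n = usable.sum(axis=-1)

    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(usable, np.log(np.where(usable, data, 1.0)), 0.0)
    w = usable.astype(float)
    sum_w = w.sum(axis=-1)
    sum_t = (w * te).sum(axis=-1)
    sum_y = logs.sum(axis=-1)
    sum_tt = (w * te**2).sum(axis=-1)
    sum_ty = (logs * te).sum(axis=-1)

    denom = sum_w * sum_tt - sum_t**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sum_w * sum_ty - sum_t * sum_y) / denom
        intercept = (sum_y - slope * sum_t) / sum_w

    valid = (n >= min_echoes) & (denom > 0)
    slope = np.where(valid, slope, 0.0)
    intercept = np.where(valid, intercept, 0.0)

    r2star = -slope
    clamped = valid & (r2star < 0)
    r2star = np.where(clamped, 0.0, r2star)
    return R2StarFit(
        r2star=r2star, ln_s0=intercept, valid_mask=valid, clamped_mask=clamped
    )


def fit_r2star(volume: MultiEchoVolume, min_echoes: int = 3) -> R2StarFit:
    """Estimate R2* by linear fitting of ln S(t) = ln S0 - t*R2*.

    The fit runs over all echoes of the volume (eight for the PD-weighted
    protocol).  Negative fitted rates are clamped to zero and flagged in
    ``clamped_mask``; voxels with fewer than ``min_echoes`` positive echoes
    are marked invalid.
    """
    if volume.protocol.n_echoes < min_echoes:
        raise ValueError(
            f"need at least {min_echoes} echoes for a decay fit, "
            f"got {volume.protocol.n_echoes}"
        )
    return _masked_ols_decay(volume.data, np.asarray(volume.protocol.echo_times), min_echoes)


def extrapolate_te0(volume: MultiEchoVolume) -> tuple[np.ndarray, np.ndarray]:
    """TE=0 amplitude of a contrast, free of R2* weighting.

    Returns ``(amplitude, valid_mask)``.  For multi-echo input the
    amplitude is exp(ln S0) from the log-linear decay fit; for a
    single-echo volume the amplitude is that echo's signal and the voxel is
    flagged (no decay correction possible).
    """
    if volume.protocol.n_echoes == 1:
        amp = volume.data[..., 0].copy()
        return amp, np.zeros(amp.shape, dtype=bool)
    if volume.protocol.n_echoes == 2:
        # Two points determine the line exactly; still no redundancy check.
        fit = _masked_ols_decay(volume.data, np.asarray(volume.protocol.echo_times), min_echoes=2)
    else:
        fit = fit_r2star(volume)
    return np.exp(fit.ln_s0) * fit.valid_mask + volume.data[..., 0] * ~fit.valid_mask, fit.valid_mask


def estimate_a_r1(
    s_pd_te0: np.ndarray,
    s_t1_te0: np.ndarray,
    proto_pd: AcquisitionProtocol,
    proto_t1: AcquisitionProtocol,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form A and R1 from the dual-flip-angle amplitude pair.

    Under the rational small-angle model the two contrasts give two
    equations in the two unknowns, solved exactly by::

        R1 = (S_T1*a_T1/TR_T1 - S_PD*a_PD/TR_PD) / (2*(S_PD/a_PD - S_T1/a_T1))
        A  = S_PD/a_PD + S_PD*a_PD / (2*TR_PD*R1)

    Returns ``(a_map, r1_map, valid_mask)``.  Voxels with a non-positive
    denominator or non-positive R1 (noise pushing the pair outside the
    model's range) are marked invalid.
    """
    if proto_pd.mt_on or proto_t1.mt_on:
        raise ValueError("A/R1 estimation requires MT-off protocols")
    if np.isclose(proto_pd.flip_angle, proto_t1.flip_angle):
        raise ValueError("flip angles must differ (dual-angle system is degenerate)")
    s_pd = np.asarray(s_pd_te0, dtype=float)
    s_t1 = np.asarray(s_t1_te0, dtype=float)
    if s_pd.shape != s_t1.shape:
        raise ValueError("amplitude fields must share one grid")

    a_pd, tr_pd = proto_pd.flip_angle, proto_pd.tr
    a_t1, tr_t1 = proto_t1.flip_angle, proto_t1.tr

    denom = 2.0 * (s_pd / a_pd - s_t1 / a_t1)
    numer = s_t1 * a_t1 / tr_t1 - s_pd * a_pd / tr_pd
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = numer / denom
        a = s_pd / a_pd + s_pd * a_pd / (2.0 * tr_pd * r1)

    valid = (denom > 0) & (r1 > 0) & np.isfinite(r1) & (s_pd > 0) & (s_t1 > 0)
    r1 = np.where(valid, r1, 0.0)
    a = np.where(valid, a, 0.0)
    return a, r1, valid


def compute_mtsat(
    s_mt_te0: np.ndarray,
    a_map: np.ndarray,
    r1_map: np.ndarray,
    proto_mt: AcquisitionProtocol,
) -> tuple[np.ndarray, np.ndarray]:
    """MT saturation per TR: delta = (A*alpha/S_MT - 1)*R1*TR - alpha^2/2.

    Evaluated with the MT-weighted protocol's flip angle and TR.  Returns
    ``(mtsat_map, valid_mask)``; voxels with S_MT <= 0 or delta outside
    [0, 1) are flagged invalid.  delta is stored as a fraction; reports
    display percent units.
    """
    if not proto_mt.mt_on:
        raise ValueError("compute_mtsat requires the MT-on protocol")
    s_mt = np.asarray(s_mt_te0, dtype=float)
    a_map = np.asarray(a_map, dtype=float)
    r1_map = np.asarray(r1_map, dtype=float)
    if not (s_mt.shape == a_map.shape == r1_map.shape):
        raise ValueError("inputs must share one grid")

    alpha, tr = proto_mt.flip_angle, proto_mt.tr
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (a_map * alpha / s_mt - 1.0) * r1_map * tr - alpha**2 / 2.0
    valid = (s_mt > 0) & np.isfinite(delta) & (delta >= 0) & (delta < 1)
    delta = np.where(valid, delta, 0.0)
    return delta, valid


def fit_quantitative_maps(
    pdw: MultiEchoVolume, t1w: MultiEchoVolume, mtw: MultiEchoVolume
) -> QuantitativeMaps:
    """Full map-fitting chain for one subject's three contrasts.

    R2* comes from the PD-weighted echo train (the longest); the TE=0
    amplitudes of all three contrasts feed the dual-angle A/R1 solution and
    the MT-saturation estimator.  The returned valid mask is the
    intersection of all per-step masks.
    """
    shapes = {v.data.shape[:3] for v in (pdw, t1w, mtw)}
    if len(shapes) != 1:
        raise ValueError("contrasts must share one spatial grid")

    r2_fit = fit_r2star(pdw)
    s_pd, v_pd = extrapolate_te0(pdw)
    s_t1, v_t1 = extrapolate_te0(t1w)
    s_mt, v_mt = extrapolate_te0(mtw)
    a_map, r1_map, v_ar1 = estimate_a_r1(s_pd, s_t1, pdw.protocol, t1w.protocol)
    mtsat, v_delta = compute_mtsat(s_mt, a_map, r1_map, mtw.protocol)

    valid = r2_fit.valid_mask & v_pd & v_t1 & v_mt & v_ar1 & v_delta
    return QuantitativeMaps(
        a=a_map,
        r1=r1_map,
        mtsat=mtsat,
        r2star=r2_fit.r2star,
        ln_s0=r2_fit.ln_s0,
        valid_mask=valid,
    )
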
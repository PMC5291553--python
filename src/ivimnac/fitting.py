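"""Segmented (two-stage) IVIM estimation.

Stage 1 estimates the true diffusion coefficient D from the high-b portion
of the decay (b > 200 s/mm^2 by default), where the fast pseudo-diffusion
pool has decayed away and the signal is monoexponential:

    S(b) = S0 * (1 - f) * exp(-b * D)      for b >> 1/D*

fitted by ordinary least squares on ln S(b) versus b; the perfusion
fraction follows from the intercept via (1 - f) = exp(intercept) / S(0).

Stage 2 then fits the full biexponential on all b values with D held fixed,
freeing (D*, f, S0) under box constraints, using damped least squares.
When the stage-1 perfusion fraction falls below a floor the perfusion term
carries no information and D* is declared unidentifiable rather than fitted.

The two stages compose into a per-voxel fit and a map-level driver applied
pixel-by-pixel inside a mask.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .model import BValueScheme, IVIMParams, SignalDecay, ValidationError

__all__ = [
    "FitResult",
    "ParameterMaps",
    "InsufficientDataError",
    "fit_high_b",
    "fit_perfusion",
    "fit_voxel",
    "fit_parameter_maps",
    "B_THRESHOLD",
    "DSTAR_MAX",
    "F_FLOOR",
]

logger = logging.getLogger(__name__)

#: Stage-1/2 defaults.  The high-b cut is strictly exclusive, so the default
#: 12-b scheme contributes {400, 800, 1000} s/mm^2 to stage 1.
B_THRESHOLD = 200.0      # s/mm^2
DSTAR_MAX = 0.5          # mm^2/s, upper box bound for D*
DSTAR_INIT = 10e-3       # mm^2/s, stage-2 initial value
F_MAX = 0.6              # stage-2 upper bound on the perfusion fraction
F_FLOOR = 0.01           # below this stage-1 f, D* is unidentifiable
D_FLOOR = 1e-6           # mm^2/s, positivity clamp for stage-1 D
SIGNAL_EPS = 1e-12       # residual floor for zero signals under noise
MAX_ITER = 500
SSE_RTOL = 1e-10


class InsufficientDataError(ValidationError):
    """Fewer than two usable high-b points for the log-linear stage."""


@dataclass(frozen=True)
class FitResult:
    """Outcome of a segmented voxel fit.

    ``converged`` is False when stage 2 was skipped (unidentifiable
    perfusion) or hit its iteration cap; the params then carry the stage-1
    values with ``D_star`` set to NaN in the unidentifiable case.
    """

    params: IVIMParams
    converged: bool
    sse: float
    n_high_b: int


@dataclass
class ParameterMaps:
    """Voxel-wise IVIM parameter fields on a common 3D grid.

    Out-of-mask voxels hold NaN.  ``converged_mask`` is a subset of
    ``fit_mask``.
    """

    D: np.ndarray
    D_star: np.ndarray
    f: np.ndarray
    S0: np.ndarray
    fit_mask: np.ndarray
    converged_mask: np.ndarray

    def __post_init__(self) -> None:
        shape = self.D.shape
        for name in ("D_star", "f", "S0", "fit_mask", "converged_mask"):
            if getattr(self, name).shape != shape:
                raise ValidationError(f"{name} shape mismatch")
        if np.any(self.converged_mask & ~self.fit_mask):
            raise ValidationError("converged_mask must be a subset of fit_mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.D.shape

    @classmethod
    def empty(cls, shape: tuple[int, int, int]) -> "ParameterMaps":
        nan = np.full(shape, np.nan)
        false = np.zeros(shape, dtype=bool)
        return cls(nan.copy(), nan.copy(), nan.copy(), nan.copy(), false.copy(), false.copy())


def fit_high_b(
    decay: SignalDecay, b_threshold: float = B_THRESHOLD
) -> tuple[float, float, float]:
    """Stage 1: log-linear fit over b > ``b_threshold``.

    Returns ``(D, f, S0_tissue)`` where ``S0_tissue = S0 * (1 - f)`` is the
    extrapolated tissue-pool intercept.  Non-positive signals are excluded
    point-wise; fewer than two surviving points raises
    :class:`InsufficientDataError`.  D is clamped positive and f to [0, 1].
    """
    b = decay.scheme.b
    sig = decay.signal
    s0 = decay.s0
    if s0 <= 0:
        raise InsufficientDataError("signal at b=0 must be positive")
    sel = (b > b_threshold) & (sig > 0)
    if int(sel.sum()) < 2:
        raise InsufficientDataError(
            f"need >= 2 positive signals above b={b_threshold:g}, got {int(sel.sum())}"
        )
    slope, intercept = np.polyfit(b[sel], np.log(sig[sel]), 1)
    d = max(-float(slope), D_FLOOR)
    f = 1.0 - math.exp(float(intercept)) / s0
    f = min(max(f, 0.0), 1.0)
    return d, f, math.exp(float(intercept))


def fit_perfusion(
    decay: SignalDecay,
    fixed: tuple[float, float, float],
    dstar_max: float = DSTAR_MAX,
    f_floor: float = F_FLOOR,
) -> FitResult:
    """Stage 2: constrained nonlinear fit of (D*, f, S0) with D fixed.

    ``fixed`` is the stage-1 triple ``(D, f, S0_tissue)``.  The residuals
    are the biexponential model minus the measured decay over all b values;
    D* is box-constrained to [D, dstar_max] and f to [0, 0.6].  If stage-1
    f is below ``f_floor`` the perfusion term has no leverage and the fit
    is skipped: D* comes back NaN and ``converged`` False.
    """
    d, f1, s0_tissue = fixed
    b = decay.scheme.b
    sig = np.maximum(decay.signal, SIGNAL_EPS)
    n_high = int((b > B_THRESHOLD).sum())

    if f1 < f_floor:
        s0 = s0_tissue / (1.0 - f1) if f1 < 1.0 else decay.s0
        params = IVIMParams(D=d, D_star=float("nan"), f=f1, S0=max(s0, SIGNAL_EPS))
        resid = params.S0 * (1.0 - f1) * np.exp(-b * d) + params.S0 * f1 - sig
        with np.errstate(over="ignore"):
            sse = float(resid @ resid)
        return FitResult(params=params, converged=False, sse=sse, n_high_b=n_high)

    s0_init = decay.s0

    def residuals(theta: np.ndarray) -> np.ndarray:
        d_star, f, s0 = theta
        return s0 * (f * np.exp(-b * d_star) + (1.0 - f) * np.exp(-b * d)) - sig

    lower = np.array([d, 0.0, SIGNAL_EPS])
    upper = np.array([dstar_max, F_MAX, np.inf])
    x0 = np.clip(np.array([DSTAR_INIT, f1, s0_init]), lower, upper)
    sol = least_squares(
        residuals,
        x0,
        bounds=(lower, upper),
        method="trf",
        xtol=SSE_RTOL,
        ftol=SSE_RTOL,
        gtol=SSE_RTOL,
        max_nfev=MAX_ITER * 3,
    )
    d_star, f, s0 = (float(v) for v in sol.x)
    d_star = min(max(d_star, d), dstar_max)
    params = IVIMParams(D=d, D_star=d_star, f=min(max(f, 0.0), 1.0), S0=s0)
    converged = bool(sol.status > 0)
    return FitResult(
        params=params, converged=converged, sse=float(2.0 * sol.cost), n_high_b=n_high
    )


def fit_voxel(
    decay: SignalDecay,
    b_threshold: float = B_THRESHOLD,
    dstar_max: float = DSTAR_MAX,
    f_floor: float = F_FLOOR,
) -> FitResult:
    """Segmented per-voxel fit: stage 1 then stage 2.

    A stage-1 failure (too few usable high-b points) yields an all-missing,
    unconverged result rather than an exception, so map-level drivers can
    sweep noisy data without guarding every voxel.
    """
    try:
        fixed = fit_high_b(decay, b_threshold=b_threshold)
    except InsufficientDataError:
        params = IVIMParams(D=D_FLOOR, D_star=float("nan"), f=0.0, S0=max(decay.s0, SIGNAL_EPS))
        return FitResult(params=params, converged=False, sse=float("nan"), n_high_b=0)
    return fit_perfusion(decay, fixed, dstar_max=dstar_max, f_floor=f_floor)


def fit_parameter_maps(
    volume: np.ndarray,
    scheme: BValueScheme,
    mask: np.ndarray,
    b_threshold: float = B_THRESHOLD,
    dstar_max: float = DSTAR_MAX,
    f_floor: float = F_FLOOR,
) -> ParameterMaps:
    """Apply the segmented fit pixel-by-pixel inside a mask.

    ``volume`` is a 4D array whose last axis runs over the b values of
    ``scheme``; ``mask`` selects the voxels to fit.  Out-of-mask voxels are
    NaN in all maps.  Logs the attempted/converged voxel counts.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.ndim != 4 or volume.shape[-1] != len(scheme):
        raise ValidationError(
            f"volume must be 4D with last axis length {len(scheme)}, got {volume.shape}"
        )
    if mask.shape != volume.shape[:3]:
        raise ValidationError(f"mask shape {mask.shape} != spatial grid {volume.shape[:3]}")

    maps = ParameterMaps.empty(volume.shape[:3])
    idx = np.argwhere(mask)
    n_conv = 0
    for i, j, k in idx:
        decay = SignalDecay(scheme=scheme, signal=np.clip(volume[i, j, k], 0.0, None))
        res = fit_voxel(decay, b_threshold=b_threshold, dstar_max=dstar_max, f_floor=f_floor)
        p = res.params
        maps.D[i, j, k] = p.D
        maps.D_star[i, j, k] = p.D_star
        maps.f[i, j, k] = p.f
        maps.S0[i, j, k] = p.S0
        maps.fit_mask[i, j, k] = True
        if res.converged:
            maps.converged_mask[i, j, k] = True
            n_conv += 1
    logger.info("fit_parameter_maps: attempted %d voxels, %d converged", len(idx), n_conv)
    return maps
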
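"""Voxel-wise estimators for the diffusion signal models.

- mono-exponential: weighted log-linear least squares (weights S^2 to
  undo the log-transform noise distortion);
- diffusion tensor: iterative weighted linear least squares with
  residual-z-score outlier rejection;
- bi- and tri-exponential: bound-constrained nonlinear least squares
  with cascaded initialization (high-b mono fit -> bi-exp -> tri-exp).

All diffusivities in the public API are in 1e-3 mm^2/s, b in s/mm^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from renodiff.exceptions import FitError, ValidationError
from renodiff.io_formats import AcquisitionScheme
from renodiff.signal_models import (
    DIFF_SCALE,
    D_FAST_DEFAULT,
    D_INTERM_DEFAULT,
    D_STAR_DEFAULT,
    BiExpParams,
    MonoParams,
    TensorFit,
    TriExpParams,
)

log = logging.getLogger(__name__)

MODELS = ("mono", "tensor", "biexp", "triexp")

#: default parameter bounds, units 1e-3 mm^2/s for diffusivities
DEFAULT_BOUNDS = {
    "D_mono": (0.0, 4.0),
    "D_bi": (0.0, 4.0),
    "D_tri": (0.0, 4.0),
    "D_interm": (3.0, 15.0),
    "D_fast": (15.0, 500.0),
    "D_star": (15.0, 500.0),
    "fraction": (0.0, 1.0),
}


@dataclass(frozen=True)
class FitConfig:
    """Configuration shared by all voxel-wise fitters."""

    model: str = "triexp"
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    max_iterations: int = 10
    tolerance: float = 1e-10
    outlier_z: float = 3.0
    averaging: str = "geometric"  # {geometric, arithmetic, none}
    pseudo_diffusion: str = "fixed"  # {fixed, free}
    initialization: str = "cascaded"  # {cascaded, flat}
    d_fast: float = D_FAST_DEFAULT
    d_interm: float = D_INTERM_DEFAULT
    d_star: float = D_STAR_DEFAULT

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValidationError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be > 0")
        if self.averaging not in ("geometric", "arithmetic", "none"):
            raise ValidationError(f"unknown averaging mode {self.averaging!r}")
        if self.pseudo_diffusion not in ("fixed", "free"):
            raise ValidationError(f"unknown pseudo-diffusion mode {self.pseudo_diffusion!r}")
        if self.initialization not in ("cascaded", "flat"):
            raise ValidationError(f"unknown initialization {self.initialization!r}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValidationError(f"bounds for {name} must satisfy lower < upper")


@dataclass(frozen=True)
class VoxelFitResult:
    """Parameter estimates plus fit diagnostics for a single voxel."""

    params: object
    rss: float
    converged: bool
    n_iterations: int
    n_rejected: int = 0


# ---------------------------------------------------------------------------
# direction handling


def average_directions(signals, scheme: AcquisitionScheme, mode: str = "geometric"):
    """Collapse multi-direction data to one signal per unique b-value.

    Geometric mode averages log-signals (exact for balanced direction
    sets on tensor data); if any signal in a shell is non-positive it
    falls back to the arithmetic mean for that shell with a warning.
    Returns ``(per_b_signal, unique_bvalues)``.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != len(scheme):
        raise ValidationError(
            f"{signals.shape[-1]} signals but scheme lists {len(scheme)} volumes"
        )
    if mode == "none":
        return signals, np.asarray(scheme.bvalues)
    ub = scheme.unique_bvalues
    out = np.empty(len(ub))
    for i, b in enumerate(ub):
        shell = signals[scheme.bvalues == b]
        if mode == "geometric":
            if np.all(shell > 0):
                out[i] = np.exp(np.mean(np.log(shell)))
            else:
                log.warning(
                    "non-positive signal at b=%g; falling back to arithmetic mean", b
                )
                out[i] = np.mean(shell)
        elif mode == "arithmetic":
            out[i] = np.mean(shell)
        else:
            raise ValidationError(f"unknown averaging mode {mode!r}")
    return out, ub


# ---------------------------------------------------------------------------
# mono-exponential


def _weighted_loglinear(signals, bvalues):
    """WLS of log-signal on b with weights S^2; returns (S0, D) unclipped."""
    y = np.log(signals)
    w = signals  # sqrt of the S^2 weights
    A = np.stack([np.ones_like(bvalues), -bvalues * DIFF_SCALE], axis=1)
    coef, *_ = np.linalg.lstsq(A * w[:, None], y * w, rcond=None)
    return float(np.exp(coef[0])), float(coef[1])


def fit_mono(signals, bvalues, config: Optional[FitConfig] = None) -> VoxelFitResult:
    """Weighted log-linear least-squares fit of the mono-exponential model."""
    config = config or FitConfig(model="mono")
    signals = np.asarray(signals, dtype=float)
    bvalues = np.asarray(bvalues, dtype=float)
    if len(signals) != len(bvalues):
        raise ValidationError("signals and bvalues must have equal length")
    if np.any(signals <= 0):
        raise ValidationError("mono fit requires strictly positive signals")
    if len(np.unique(bvalues)) < 2:
        raise FitError("mono fit needs at least 2 distinct b-values")
    s0, d = _weighted_loglinear(signals, bvalues)
    lo, hi = config.bounds["D_mono"]
    d = float(np.clip(d, lo, hi))
    params = MonoParams(S0=s0, D_mono=d)
    pred = s0 * np.exp(-bvalues * d * DIFF_SCALE)
    rss = float(np.sum((signals - pred) ** 2))
    return VoxelFitResult(params=params, rss=rss, converged=True, n_iterations=1)


# ---------------------------------------------------------------------------
# tensor


def _tensor_design(scheme: AcquisitionScheme) -> np.ndarray:
    b = scheme.bvalues * DIFF_SCALE
    g = scheme.directions
    return np.stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )


def _clip_psd(m: np.ndarray) -> np.ndarray:
    lam, v = np.linalg.eigh(m)
    lam = np.clip(lam, 0.0, None)
    return (v * lam) @ v.T


def fit_tensor_wlls(signals, scheme: AcquisitionScheme, config: Optional[FitConfig] = None) -> VoxelFitResult:
    """Iterative WLS tensor fit with residual-z-score outlier rejection.

    Each iteration solves a linear WLS on the log-signal with weights
    equal to the squared predicted signal, standardizes the weighted
    residuals, and drops measurements with |z| above the configured
    threshold.  Stops when the estimate stabilizes or after
    ``max_iterations``.  Raises :class:`FitError` when fewer than 7
    usable measurements remain.
    """
    config = config or FitConfig(model="tensor")
    signals = np.asarray(signals, dtype=float)
    if len(signals) != len(scheme):
        raise ValidationError("signals and scheme must have equal length")
    usable = np.isfinite(signals) & (signals > 0)
    if usable.sum() < 7:
        raise FitError(f"only {int(usable.sum())} usable measurements; need >= 7")
    X = _tensor_design(scheme)
    y = np.log(signals, out=np.full_like(signals, np.nan), where=usable)

    include = usable.copy()
    beta = None
    n_iter = 0
    converged = False
    for n_iter in range(1, config.max_iterations + 1):
        Xi, yi = X[include], y[include]
        if include.sum() < 7 or np.linalg.matrix_rank(Xi) < 7:
            raise FitError(
                f"only {int(include.sum())} usable measurements after rejection; need >= 7"
            )
        if beta is None:  # first pass: ordinary LS to seed the weights
            beta = np.linalg.lstsq(Xi, yi, rcond=None)[0]
        w = np.exp(Xi @ beta)  # sqrt-weights = predicted signal
        beta_new = np.linalg.lstsq(Xi * w[:, None], yi * w, rcond=None)[0]

        # standardized weighted residuals over currently included points
        resid = np.full(len(signals), np.nan)
        resid[include] = (yi - Xi @ beta_new) * w
        scale = np.nanstd(resid[include], ddof=7)
        if not np.isfinite(scale) or scale < 1e-12 * max(1.0, float(np.nanmax(np.abs(w)))):
            outliers = np.zeros(len(signals), dtype=bool)
        else:
            with np.errstate(invalid="ignore"):
                outliers = np.abs(resid) > config.outlier_z * scale
        outliers &= include

        stable = np.max(np.abs(beta_new - beta)) < config.tolerance
        beta = beta_new
        if not outliers.any() and stable:
            converged = True
            break
        if outliers.any():
            include &= ~outliers
        elif stable:
            converged = True
            break

    s0 = float(np.exp(beta[0]))
    m = np.array(
        [
            [beta[1], beta[4], beta[5]],
            [beta[4], beta[2], beta[6]],
            [beta[5], beta[6], beta[3]],
        ]
    )
    m = _clip_psd(m)  # design absorbs the 1e-3 scale: elements are 1e-3 mm^2/s
    params = TensorFit.from_matrix(s0, m)
    pred = np.exp(X @ beta)
    rss = float(np.sum((signals[include] - pred[include]) ** 2))
    return VoxelFitResult(
        params=params,
        rss=rss,
        converged=converged,
        n_iterations=n_iter,
        n_rejected=int(usable.sum() - include.sum()),
    )


# ---------------------------------------------------------------------------
# bi-exponential


def _mono_seed(signals, bvalues, config, b_min=200.0):
    """High-b mono fit seeding the tissue compartment."""
    hi = bvalues >= b_min
    if np.sum(hi) >= 2 and len(np.unique(bvalues[hi])) >= 2:
        s0t, d = _weighted_loglinear(signals[hi], bvalues[hi])
    else:
        s0t, d = _weighted_loglinear(signals, bvalues)
    lo, up = config.bounds["D_bi"]
    return s0t, float(np.clip(d, lo + 1e-6, up - 1e-6))


def fit_biexp(signals, bvalues, config: Optional[FitConfig] = None) -> VoxelFitResult:
    """Bound-constrained NLLS fit of the bi-exponential model.

    In ``fixed`` pseudo-diffusion mode D_star is held at the configured
    value and only (S0, f_star, D_bi) are free; in ``free`` mode D_star
    is estimated within its bounds.  The bound boxes keep
    D_star > D_bi by construction.
    """
    config = config or FitConfig(model="biexp")
    signals = np.asarray(signals, dtype=float)
    bvalues = np.asarray(bvalues, dtype=float)
    ub = np.unique(bvalues)
    if len(ub) < 4 or ub.min() > 0 or ub.max() < 500:
        raise ValidationError(
            "bi-exp fit needs >= 4 distinct b-values including b=0 and b >= 500"
        )
    if np.any(signals <= 0):
        raise ValidationError("bi-exp fit requires strictly positive signals")

    fixed = config.pseudo_diffusion == "fixed"
    d_lo, d_hi = config.bounds["D_bi"]
    ds_lo, ds_hi = config.bounds["D_star"]
    s_max = float(signals.max())

    def model(x):
        if fixed:
            s0, f, d = x
            dstar = config.d_star
        else:
            s0, f, d, dstar = x
        return s0 * (
            f * np.exp(-bvalues * dstar * DIFF_SCALE)
            + (1 - f) * np.exp(-bvalues * d * DIFF_SCALE)
        )

    def resid(x):
        return model(x) - signals

    def starts():
        if config.initialization == "cascaded":
            s0t, d0 = _mono_seed(signals, bvalues, config)
            s0_meas = float(np.mean(signals[bvalues == bvalues.min()]))
            f0 = float(np.clip(1.0 - s0t / max(s0_meas, 1e-30), 1e-3, 0.6))
            yield [s0_meas, f0, d0]
        # flat start: midpoint of bounds (also the cascaded fallback)
        yield [s_max, 0.5, 0.5 * (d_lo + d_hi)]

    lo = [0.0, 0.0, d_lo]
    hi = [10.0 * s_max, 1.0, d_hi]
    if not fixed:
        lo.append(ds_lo)
        hi.append(ds_hi)

    best = None
    for x0 in starts():
        if not fixed:
            x0 = x0 + [config.d_star]
        x0 = np.clip(x0, lo, hi)
        sol = least_squares(
            resid, x0, bounds=(lo, hi), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost <= config.tolerance:
            break

    x = best.x
    dstar = config.d_star if fixed else float(x[3])
    dbi = min(float(x[2]), dstar - 1e-9)
    params = BiExpParams(S0=float(x[0]), f_star=float(x[1]), D_star=dstar, D_bi=dbi)
    return VoxelFitResult(
        params=params,
        rss=float(2 * best.cost),
        converged=bool(best.success),
        n_iterations=int(best.nfev),
    )


# ---------------------------------------------------------------------------
# tri-exponential


def fit_triexp(signals, bvalues, config: Optional[FitConfig] = None) -> VoxelFitResult:
    """Bound-constrained NLLS fit of the three-compartment model.

    The fraction-sum constraint f_fast + f_interm <= 1 is enforced by
    reparameterizing f_interm = u * (1 - f_fast) with u in [0, 1].  In
    ``fixed`` mode D_fast and D_interm stay at their configured values;
    ``free`` mode estimates them inside their (disjoint, ordered)
    bound boxes.  Initialization cascades from the bi-exponential fit.
    """
    config = config or FitConfig(model="triexp")
    signals = np.asarray(signals, dtype=float)
    bvalues = np.asarray(bvalues, dtype=float)
    if len(np.unique(bvalues)) < 6:
        raise ValidationError("tri-exp fit needs >= 6 distinct b-values")
    if np.any(signals <= 0):
        raise ValidationError("tri-exp fit requires strictly positive signals")

    fixed = config.pseudo_diffusion == "fixed"
    dt_lo, dt_hi = config.bounds["D_tri"]
    di_lo, di_hi = config.bounds["D_interm"]
    df_lo, df_hi = config.bounds["D_fast"]
    s_max = float(signals.max())

    def unpack(x):
        if fixed:
            s0, ff, u, dt = x
            dfast, dinterm = config.d_fast, config.d_interm
        else:
            s0, ff, u, dt, dinterm, dfast = x
        fi = u * (1.0 - ff)
        return s0, ff, fi, dt, dinterm, dfast

    def resid(x):
        s0, ff, fi, dt, dinterm, dfast = unpack(x)
        pred = s0 * (
            ff * np.exp(-bvalues * dfast * DIFF_SCALE)
            + fi * np.exp(-bvalues * dinterm * DIFF_SCALE)
            + (1 - ff - fi) * np.exp(-bvalues * dt * DIFF_SCALE)
        )
        return pred - signals

    def starts():
        if config.initialization == "cascaded":
            try:
                be = fit_biexp(signals, bvalues, replace(config, model="biexp")).params
                ff0 = float(np.clip(be.f_star, 1e-3, 0.5))
                dt0 = float(np.clip(0.9 * be.D_bi, dt_lo + 1e-6, dt_hi - 1e-6))
                yield [be.S0, ff0, 0.25, dt0]
            except (ValidationError, FitError):
                pass
        yield [s_max, 0.05, 0.25, 0.5 * (dt_lo + dt_hi)]
        yield [s_max, 0.25, 0.5, 0.5 * (dt_lo + dt_hi)]

    lo = [0.0, 0.0, 0.0, dt_lo]
    hi = [10.0 * s_max, 1.0, 1.0, dt_hi]
    if not fixed:
        lo += [di_lo, df_lo]
        hi += [di_hi, df_hi]

    best = None
    for x0 in starts():
        if not fixed:
            x0 = x0 + [config.d_interm, config.d_fast]
        x0 = np.clip(x0, lo, hi)
        sol = least_squares(
            resid, x0, bounds=(lo, hi), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost <= config.tolerance:
            break

    s0, ff, fi, dt, dinterm, dfast = unpack(best.x)
    dt = min(dt, dinterm - 1e-9)
    params = TriExpParams(
        S0=float(s0), f_fast=float(ff), D_fast=float(dfast),
        f_interm=float(fi), D_interm=float(dinterm), D_tri=float(dt),
    )
    return VoxelFitResult(
        params=params,
        rss=float(2 * best.cost),
        converged=bool(best.success),
        n_iterations=int(best.nfev),
    )


# ---------------------------------------------------------------------------
# whole-volume driver

_PARAM_NAMES = {
    "mono": ("S0", "D_mono"),
    "biexp": ("S0", "f_star", "D_star", "D_bi"),
    "triexp": ("S0", "f_fast", "D_fast", "f_interm", "D_interm", "D_tri", "f_slow"),
    "tensor": ("S0", "MD", "FA", "Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz"),
}


def _params_to_dict(model, params):
    if model == "tensor":
        from renodiff.signal_models import tensor_fa, tensor_md

        xx, yy, zz, xy, xz, yz = params.elements
        return {
            "S0": params.S0, "MD": tensor_md(params), "FA": tensor_fa(params),
            "Dxx": xx, "Dyy": yy, "Dzz": zz, "Dxy": xy, "Dxz": xz, "Dyz": yz,
        }
    out = {name: getattr(params, name) for name in _PARAM_NAMES[model]}
    return out


def fit_volume(volume4d, scheme: AcquisitionScheme, mask, config: Optional[FitConfig] = None) -> dict:
    """Apply the configured voxel fit inside a mask.

    Returns a dict of 3D maps: one per model parameter plus ``converged``
    and ``rss``.  Voxels outside the mask (or with non-finite input) are
    NaN; failed voxels carry NaN parameters and converged = 0.
    Voxels are fitted independently and sequentially, so the result is
    deterministic.
    """
    config = config or FitConfig()
    volume4d = np.asarray(volume4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume4d.ndim != 4:
        raise ValidationError("volume must be 4D")
    if mask.shape != volume4d.shape[:3]:
        raise ValidationError(
            f"mask shape {mask.shape} does not match volume grid {volume4d.shape[:3]}"
        )
    if not mask.any():
        raise ValidationError("mask is empty")
    if volume4d.shape[3] != len(scheme):
        raise ValidationError("4th dimension does not match the scheme")

    names = _PARAM_NAMES[config.model] + ("converged", "rss")
    maps = {name: np.full(mask.shape, np.nan) for name in names}

    n_skipped = 0
    for idx in np.argwhere(mask):
        i, j, k = idx
        sig = volume4d[i, j, k]
        if not np.all(np.isfinite(sig)):
            n_skipped += 1
            maps["converged"][i, j, k] = 0.0
            continue
        try:
            if config.model == "tensor":
                res = fit_tensor_wlls(sig, scheme, config)
            else:
                s, b = average_directions(sig, scheme, config.averaging)
                if config.model == "mono":
                    res = fit_mono(s, b, config)
                elif config.model == "biexp":
                    res = fit_biexp(s, b, config)
                else:
                    res = fit_triexp(s, b, config)
        except (FitError, ValidationError) as exc:
            log.debug("fit failed at voxel %s: %s", (i, j, k), exc)
            maps["converged"][i, j, k] = 0.0
            continue
        for name, value in _params_to_dict(config.model, res.params).items():
            maps[name][i, j, k] = value
        maps["converged"][i, j, k] = float(res.converged)
        maps["rss"][i, j, k] = res.rss
    if n_skipped:
        log.warning("%d masked voxels had non-finite input and were skipped", n_skipped)
    return maps
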
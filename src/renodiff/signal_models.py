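"""Forward models of the diffusion-weighted signal.

Four models of magnitude signal decay versus diffusion weighting b
(s/mm^2): mono-exponential, bi-exponential (tissue diffusion plus a
pseudo-diffusion compartment), tri-exponential (fast / intermediate /
slow compartments) and the diffusion tensor, plus mean-diffusivity and
fractional-anisotropy algebra.

Unit convention: diffusivities are expressed in 1e-3 mm^2/s everywhere in
the public API; b-values in s/mm^2.  Internally the product b*D is made
dimensionless with a factor 1e-3.  Signal fractions are proportions in
[0, 1]; tabular output converts to percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from renodiff.exceptions import ValidationError

#: scale factor turning D in 1e-3 mm^2/s times b in s/mm^2 into a pure number
DIFF_SCALE = 1.0e-3

# Pseudo-diffusion coefficients are rarely identifiable from b <= 700
# data, so the fitting layer can hold them fixed at these defaults
# (1e-3 mm^2/s): a perfusion-regime fast coefficient and an intermediate
# coefficient on the scale of free water.
D_FAST_DEFAULT = 50.0
D_INTERM_DEFAULT = 6.0
D_STAR_DEFAULT = 50.0


def _check_b(b):
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValidationError("b-values must be non-negative")
    return b


@dataclass(frozen=True)
class MonoParams:
    """Mono-exponential decay: S(b) = S0 * exp(-b * D_mono)."""

    S0: float
    D_mono: float

    def __post_init__(self):
        if self.S0 < 0:
            raise ValidationError(f"S0 must be >= 0, got {self.S0}")
        if self.D_mono < 0:
            raise ValidationError(f"D_mono must be >= 0, got {self.D_mono}")


@dataclass(frozen=True)
class BiExpParams:
    """Two-compartment decay with a pseudo-diffusion fraction.

    S(b) = S0 * [f_star * exp(-b*D_star) + (1 - f_star) * exp(-b*D_bi)]

    The ordering D_star > D_bi is an invariant: it pins the fast
    compartment label and prevents label switching during fitting.
    """

    S0: float
    f_star: float
    D_star: float
    D_bi: float

    def __post_init__(self):
        if self.S0 < 0:
            raise ValidationError(f"S0 must be >= 0, got {self.S0}")
        if not 0.0 <= self.f_star <= 1.0:
            raise ValidationError(f"f_star must lie in [0, 1], got {self.f_star}")
        if self.D_bi < 0:
            raise ValidationError(f"D_bi must be >= 0, got {self.D_bi}")
        if not self.D_star > self.D_bi:
            raise ValidationError(
                f"require D_star > D_bi, got D_star={self.D_star}, D_bi={self.D_bi}"
            )


@dataclass(frozen=True)
class TriExpParams:
    """Three-compartment decay; the slow fraction is implied.

    S(b) = S0 * [f_fast * exp(-b*D_fast) + f_interm * exp(-b*D_interm)
                 + (1 - f_fast - f_interm) * exp(-b*D_tri)]
    """

    S0: float
    f_fast: float
    D_fast: float
    f_interm: float
    D_interm: float
    D_tri: float

    def __post_init__(self):
        if self.S0 < 0:
            raise ValidationError(f"S0 must be >= 0, got {self.S0}")
        if self.f_fast < 0 or self.f_interm < 0:
            raise ValidationError("signal fractions must be >= 0")
        if self.f_fast + self.f_interm > 1.0 + 1e-12:
            raise ValidationError(
                f"f_fast + f_interm must be <= 1, got {self.f_fast + self.f_interm}"
            )
        if self.D_tri < 0:
            raise ValidationError(f"D_tri must be >= 0, got {self.D_tri}")
        if not self.D_fast > self.D_interm > self.D_tri:
            raise ValidationError(
                "require D_fast > D_interm > D_tri, got "
                f"{self.D_fast}, {self.D_interm}, {self.D_tri}"
            )

    @property
    def f_slow(self) -> float:
        return 1.0 - self.f_fast - self.f_interm


@dataclass(frozen=True)
class TensorFit:
    """S0 plus the six unique elements of a symmetric diffusion tensor.

    Element order: (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), units 1e-3 mm^2/s.
    MD and FA are always derived, never stored.
    """

    S0: float
    elements: tuple = field(default=(0.0,) * 6)

    def __post_init__(self):
        if self.S0 < 0:
            raise ValidationError(f"S0 must be >= 0, got {self.S0}")
        if len(self.elements) != 6:
            raise ValidationError("tensor needs exactly 6 unique elements")
        object.__setattr__(self, "elements", tuple(float(e) for e in self.elements))

    @property
    def matrix(self) -> np.ndarray:
        xx, yy, zz, xy, xz, yz = self.elements
        return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues in descending order."""
        return np.linalg.eigvalsh(self.matrix)[::-1]

    @classmethod
    def from_matrix(cls, S0: float, m: np.ndarray) -> "TensorFit":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3) or not np.allclose(m, m.T, atol=1e-9):
            raise ValidationError("tensor matrix must be symmetric 3x3")
        return cls(S0, (m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]))


def predict_mono(params: MonoParams, b):
    """Signal of the mono-exponential model at diffusion weighting ``b``."""
    b = _check_b(b)
    return params.S0 * np.exp(-b * params.D_mono * DIFF_SCALE)


def predict_biexp(params: BiExpParams, b):
    """Signal of the bi-exponential (pseudo-diffusion) model at ``b``."""
    b = _check_b(b)
    f = params.f_star
    return params.S0 * (
        f * np.exp(-b * params.D_star * DIFF_SCALE)
        + (1.0 - f) * np.exp(-b * params.D_bi * DIFF_SCALE)
    )


def predict_triexp(params: TriExpParams, b):
    """Signal of the three-compartment model at ``b``."""
    b = _check_b(b)
    return params.S0 * (
        params.f_fast * np.exp(-b * params.D_fast * DIFF_SCALE)
        + params.f_interm * np.exp(-b * params.D_interm * DIFF_SCALE)
        + params.f_slow * np.exp(-b * params.D_tri * DIFF_SCALE)
    )


def predict_tensor(fit: TensorFit, b, g):
    """Tensor-model signal S0 * exp(-b * g^T D g) for unit direction ``g``.

    ``b`` may be a scalar or an array; ``g`` a single 3-vector or an array
    of matching leading shape.  Directions must be unit norm wherever
    b > 0 (b = 0 entries may carry zero-vectors).
    """
    scalar_in = np.ndim(b) == 0 and np.ndim(g) == 1
    b = _check_b(b)
    g = np.asarray(g, dtype=float)
    g2 = np.atleast_2d(g)
    b1 = np.atleast_1d(b)
    n = max(b1.shape[0], g2.shape[0])
    b1 = np.broadcast_to(b1, (n,))
    g2 = np.broadcast_to(g2, (n, 3))
    norms = np.linalg.norm(g2, axis=1)
    bad = (b1 > 0) & (np.abs(norms - 1.0) > 1e-6)
    if np.any(bad):
        raise ValidationError("gradient directions must be unit norm where b > 0")
    quad = np.einsum("ij,jk,ik->i", g2, fit.matrix, g2)
    out = fit.S0 * np.exp(-b1 * quad * DIFF_SCALE)
    return float(out[0]) if scalar_in else out


def tensor_md(fit: TensorFit) -> float:
    """Mean diffusivity: one third of the tensor trace."""
    xx, yy, zz = fit.elements[:3]
    return (xx + yy + zz) / 3.0


def tensor_fa(fit: TensorFit) -> float:
    """Fractional anisotropy from the tensor eigenvalues.

    FA = sqrt(3/2) * sqrt(sum((lam_i - MD)^2) / sum(lam_i^2)), in [0, 1]
    for PSD tensors.  Raises for the all-zero tensor, where FA is
    undefined.
    """
    lam = fit.eigenvalues()
    denom = float(np.sum(lam**2))
    if denom == 0.0:
        raise ValidationError("FA undefined for the zero tensor")
    md = float(np.mean(lam))
    fa = float(np.sqrt(1.5 * np.sum((lam - md) ** 2) / denom))
    return min(fa, 1.0)


def tensor_from_md_fa(md: float, fa: float, axis=(0.0, 0.0, 1.0), S0: float = 1.0) -> TensorFit:
    """Axially symmetric tensor with prescribed MD and FA.

    Eigenvalues are (md*(1+2d), md*(1-d), md*(1-d)) with the anisotropy
    d = FA / sqrt(3 - 2 FA^2), which solves the FA equation exactly; the
    distinct eigenvalue is aligned with ``axis``.
    """
    if not 0.0 <= fa < 1.0 + 1e-12:
        raise ValidationError(f"FA must lie in [0, 1], got {fa}")
    if md < 0:
        raise ValidationError(f"MD must be >= 0, got {md}")
    fa = min(fa, 1.0)
    d = fa / np.sqrt(3.0 - 2.0 * fa**2)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    lam_par = md * (1.0 + 2.0 * d)
    lam_perp = md * (1.0 - d)
    m = lam_perp * np.eye(3) + (lam_par - lam_perp) * np.outer(axis, axis)
    return TensorFit.from_matrix(S0, m)
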
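"""Multiscale Hessian eigen-analysis and the five-feature vesselness bank.

For a bright tube on a dark background the Hessian of a Gaussian-smoothed
image has, on the axis, one eigenvalue near zero (along the vessel) and two
strongly negative ones (across it). The five classical responses built from
those eigenvalues — Sato (f1), Frangi (f2), Shikata (f3), Li (f4) and the
Manniesing diffusion-style response (f5) — form the per-voxel, per-scale
feature vector consumed by the cascade classifier. The bank deliberately
embeds shape and scale redundancy: no single response covers blurred
boundaries, stenoses and vessel-like distractors at once.

Conventions
-----------
* Eigenvalues are sorted by *signed* value, λ1 ≥ λ2 ≥ λ3 (descending).
  Frangi-style ratios need magnitude ordering; :func:`magnitude_view`
  provides the |λm1| ≤ |λm2| ≤ |λm3| permutation.
* Hessian components are computed in mm⁻² (spacing-aware derivatives) and
  scale-normalized by σ² so responses are comparable across scales. f3 is
  the exception: it is defined on the raw eigenvalue with an explicit σ²
  factor, which algebraically equals the normalized eigenvalue divided by
  intensity.
* Smoothing scales follow the geometric bank σ_r = 0.6 · 2^((i−1)/2) mm,
  i = 1..6, covering vessel radii from sub-millimetre to several mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "ScaleBank",
    "FeatureParams",
    "EigenSystem",
    "FeatureField",
    "default_scale_bank",
    "hessian_at_scale",
    "eigen_sorted",
    "eigenvalues_analytic",
    "magnitude_view",
    "sato_f1",
    "frangi_f2",
    "frangi_gamma",
    "shikata_f3",
    "li_f4",
    "manniesing_f5",
    "multiscale_features",
]

N_FEATURES = 5

# Unique Hessian components, index order used throughout the module.
_COMP_ORDER = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


class FeatureComputationError(ValueError):
    """Raised for under-resolved scales, non-finite input or degenerate fields."""


@dataclass(frozen=True)
class ScaleBank:
    """Ordered list of smoothing scales σ_r in mm (strictly increasing)."""

    sigmas: tuple[float, ...]

    def __post_init__(self) -> None:
        sig = tuple(float(s) for s in self.sigmas)
        if len(sig) == 0 or any(s <= 0 for s in sig):
            raise ValueError("scales must be positive")
        if any(b <= a for a, b in zip(sig, sig[1:])):
            raise ValueError("scales must be strictly increasing")
        object.__setattr__(self, "sigmas", sig)

    def __len__(self) -> int:
        return len(self.sigmas)


def default_scale_bank(base: float = 0.6, count: int = 6) -> ScaleBank:
    """Geometric scale bank σ_r = base · 2^((i−1)/2), i = 1..count."""
    return ScaleBank(tuple(base * 2 ** (i / 2) for i in range(count)))


@dataclass(frozen=True)
class FeatureParams:
    """Parameters of the five vesselness responses.

    ``frangi_gamma=None`` requests per-scale auto-estimation (half the maximum
    Frobenius norm of that scale's Hessian field). The Manniesing response
    keeps its own fixed γ by default.
    """

    sato_alpha1: float = 0.5
    sato_alpha2: float = 2.0
    frangi_alpha: float = 0.5
    frangi_beta: float = 0.5
    frangi_gamma: float | None = None
    manniesing_alpha: float = 0.5
    manniesing_beta: float = 0.5
    manniesing_gamma: float = 5.0
    manniesing_c: float = 1e-6
    intensity_floor_rel: float = 1e-6  # f3 guard, relative to max |I|

    def __post_init__(self) -> None:
        if not self.sato_alpha1 < self.sato_alpha2:
            raise ValueError("sato_alpha1 must be < sato_alpha2")
        for name in ("sato_alpha1", "frangi_alpha", "frangi_beta",
                     "manniesing_alpha", "manniesing_beta", "manniesing_gamma",
                     "manniesing_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.frangi_gamma is not None and self.frangi_gamma <= 0:
            raise ValueError("frangi_gamma must be positive or None (auto)")


@dataclass
class EigenSystem:
    """Signed-descending Hessian eigen-decomposition.

    ``eigenvalues[..., k]`` is λ_{k+1} with λ1 ≥ λ2 ≥ λ3;
    ``eigenvectors[..., :, k]`` is the matching unit eigenvector.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray


@dataclass
class FeatureField:
    """Per-voxel, per-scale feature 5-vectors.

    ``values[s, f]`` is the f-th feature map (f1..f5 → 0..4) at scale index s.
    ``hessians`` optionally keeps the σ²-normalized Hessian components
    (order xx, yy, zz, xy, xz, yz) per scale for downstream frame estimation.
    """

    values: np.ndarray  # (n_scales, 5, nx, ny, nz)
    scale_bank: ScaleBank
    low_intensity_count: int = 0
    hessians: np.ndarray | None = None  # (n_scales, 6, nx, ny, nz)

    @property
    def n_scales(self) -> int:
        return len(self.scale_bank)


def hessian_at_scale(volume: Volume, sigma: float, *,
                     normalized: bool = True) -> np.ndarray:
    """Gaussian-derivative Hessian components at scale ``sigma`` (mm).

    Returns an array of shape ``(6,) + volume.shape`` with the unique
    components in the order xx, yy, zz, xy, xz, yz, in mm⁻² units and
    (by default) multiplied by σ² for scale normalization. Boundary handling
    is reflect-padding.
    """
    spacing = np.asarray(volume.spacing)
    if sigma < spacing.max() / 2:
        raise FeatureComputationError(
            f"sigma={sigma} mm under-resolves spacing {volume.spacing} "
            "(needs sigma >= max(spacing)/2)")
    data = np.asarray(volume.data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise FeatureComputationError("volume contains non-finite values")
    if min(data.shape) < 8:
        raise FeatureComputationError(
            f"volume shape {data.shape} too small for feature computation")
    sigma_vox = sigma / spacing
    # second derivatives are invariant to a constant shift; centering the
    # data keeps float32 cancellation error well below the signal
    data = data - np.float32(data.mean())
    out = np.empty((6,) + data.shape, dtype=np.float32)
    norm = sigma * sigma if normalized else 1.0
    for k, (a, b) in enumerate(_COMP_ORDER):
        orders = [0, 0, 0]
        orders[a] += 1
        orders[b] += 1
        d = ndimage.gaussian_filter(data, sigma_vox, order=orders, mode="reflect")
        out[k] = d * (norm / (spacing[a] * spacing[b]))
    return out


def _components_to_matrices(comp: np.ndarray) -> np.ndarray:
    """(6, ...) component stack → (..., 3, 3) symmetric matrices."""
    xx, yy, zz, xy, xz, yz = comp
    mat = np.empty(xx.shape + (3, 3), dtype=comp.dtype)
    mat[..., 0, 0] = xx
    mat[..., 1, 1] = yy
    mat[..., 2, 2] = zz
    mat[..., 0, 1] = mat[..., 1, 0] = xy
    mat[..., 0, 2] = mat[..., 2, 0] = xz
    mat[..., 1, 2] = mat[..., 2, 1] = yz
    return mat


def eigen_sorted(hessian_field: np.ndarray, *, sym_tol: float = 1e-5) -> EigenSystem:
    """Signed-descending eigen-decomposition of a symmetric 3×3 field.

    Accepts either ``(..., 3, 3)`` matrices or a ``(6, ...)`` component stack.
    Ties keep the stable order returned by the underlying solver; for
    degenerate (repeated) eigenvalues only the eigenvalues are contractual.
    """
    field = np.asarray(hessian_field)
    if field.ndim >= 1 and field.shape[0] == 6 and (field.ndim < 2 or field.shape[-1] != 3):
        field = _components_to_matrices(field)
    if field.shape[-2:] != (3, 3):
        raise ValueError(f"expected (...,3,3) field, got shape {field.shape}")
    asym = np.abs(field - np.swapaxes(field, -1, -2)).max()
    scale = max(np.abs(field).max(), 1.0)
    if asym > sym_tol * scale:
        raise ValueError(f"input not symmetric (max asymmetry {asym:g})")
    field = 0.5 * (field + np.swapaxes(field, -1, -2))
    vals, vecs = np.linalg.eigh(field.astype(np.float64))
    # eigh returns ascending; flip to signed-descending λ1 ≥ λ2 ≥ λ3.
    return EigenSystem(vals[..., ::-1].copy(), vecs[..., ::-1].copy())


def eigenvalues_analytic(comp: np.ndarray) -> np.ndarray:
    """Closed-form signed-descending eigenvalues of a symmetric 3×3 field.

    Vectorized trigonometric solution of the characteristic cubic; an order
    of magnitude faster than LAPACK on whole-volume fields and cross-checked
    against :func:`eigen_sorted` in the test suite. Input is a ``(6, ...)``
    component stack (xx, yy, zz, xy, xz, yz); output has shape ``(..., 3)``.
    """
    xx, yy, zz, xy, xz, yz = (np.asarray(c, dtype=np.float64) for c in comp)
    q = (xx + yy + zz) / 3.0
    axx, ayy, azz = xx - q, yy - q, zz - q
    p2 = (axx * axx + ayy * ayy + azz * azz
          + 2.0 * (xy * xy + xz * xz + yz * yz)) / 6.0
    p = np.sqrt(p2)
    # det of (A - q I) / p, guarded where p == 0 (isotropic point).
    safe_p = np.where(p > 0, p, 1.0)
    bxx, byy, bzz = axx / safe_p, ayy / safe_p, azz / safe_p
    bxy, bxz, byz = xy / safe_p, xz / safe_p, yz / safe_p
    detb = (bxx * (byy * bzz - byz * byz)
            - bxy * (bxy * bzz - byz * bxz)
            + bxz * (bxy * byz - byy * bxz))
    phi = np.arccos(np.clip(detb / 2.0, -1.0, 1.0)) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    out = np.stack([e1, e2, e3], axis=-1)
    iso = p == 0
    if np.any(iso):
        out[iso] = q[iso][..., None]
    return out


def magnitude_view(eigenvalues: np.ndarray) -> np.ndarray:
    """Permute signed eigenvalues into |λm1| ≤ |λm2| ≤ |λm3| order.

    The sort is stable: exact magnitude ties keep the incoming signed order.
    """
    vals = np.asarray(eigenvalues)
    order = np.argsort(np.abs(vals), axis=-1, kind="stable")
    return np.take_along_axis(vals, order, axis=-1)


def sato_f1(lam1: np.ndarray, lam2: np.ndarray,
            alpha1: float = 0.5, alpha2: float = 2.0) -> np.ndarray:
    """Sato line response from the two signed-largest eigenvalues.

    Negative for bright tubes (λ2 < 0); the asymmetric α1/α2 penalties damp
    the response when the along-axis curvature λ1 moves away from zero. The
    sign is kept as defined — downstream interval classifiers are
    sign-agnostic.
    """
    if not 0 < alpha1 < alpha2:
        raise ValueError("need 0 < alpha1 < alpha2")
    lam1 = np.asarray(lam1, dtype=np.float64)
    lam2 = np.asarray(lam2, dtype=np.float64)
    alpha = np.where(lam1 <= 0, alpha1, alpha2)
    # the zero branch also catches subnormal lam2 whose product with alpha
    # flushes to zero (the exact response is then indistinguishable from 0)
    denom = alpha * lam2
    zero2 = (lam2 == 0) | (denom == 0)
    safe = np.where(zero2, 1.0, denom)
    with np.errstate(over="ignore"):
        ratio = lam1 / safe  # ratio form avoids underflow in lam2**2
        expo = np.exp(-0.5 * np.minimum(ratio * ratio, 745.0 * 2))
    return np.where(zero2, 0.0, lam2 * expo)


def _frangi_product(lam: np.ndarray, alpha: float, beta: float,
                    gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Shared Frangi factor; returns (product, active) with active = valid tube."""
    m = magnitude_view(lam)
    am1, am2, am3 = np.abs(m[..., 0]), np.abs(m[..., 1]), np.abs(m[..., 2])
    s2 = np.sum(lam * lam, axis=-1)
    active = am3 > 0
    safe3 = np.where(active, am3, 1.0)
    ra2 = (am2 / safe3) ** 2
    safe23 = np.where(am2 * am3 > 0, am2 * am3, 1.0)
    rb2 = (am1 * am1) / safe23
    prod = ((1.0 - np.exp(-ra2 / (2.0 * alpha * alpha)))
            * np.exp(-rb2 / (2.0 * beta * beta))
            * (1.0 - np.exp(-s2 / (2.0 * gamma * gamma))))
    return prod, active


def frangi_f2(eigenvalues: np.ndarray, alpha: float = 0.5, beta: float = 0.5,
              gamma: float = 1.0) -> np.ndarray:
    """Frangi vesselness in [0, 1] for bright tubes (λ2, λ3 < 0).

    ``eigenvalues`` are signed-descending ``(..., 3)``; ratios use the
    magnitude ordering internally.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    lam = np.asarray(eigenvalues, dtype=np.float64)
    prod, active = _frangi_product(lam, alpha, beta, gamma)
    bright = (lam[..., 1] <= 0) & (lam[..., 2] <= 0)
    return np.where(bright & active, prod, 0.0)


def frangi_gamma(hessian_field: np.ndarray) -> float:
    """Auto-estimate γ as half the maximum Frobenius norm of the Hessian field.

    Accepts ``(6, ...)`` components or ``(..., 3, 3)`` matrices.
    """
    field = np.asarray(hessian_field, dtype=np.float64)
    if field.shape[-2:] == (3, 3):
        frob2 = np.sum(field * field, axis=(-2, -1))
    elif field.ndim >= 1 and field.shape[0] == 6:
        xx, yy, zz, xy, xz, yz = field
        frob2 = xx**2 + yy**2 + zz**2 + 2 * (xy**2 + xz**2 + yz**2)
    else:
        raise ValueError(f"unrecognized hessian field shape {field.shape}")
    gmax = float(np.sqrt(frob2.max()))
    if gmax == 0:
        raise FeatureComputationError("all-zero Hessian field: degenerate image")
    return gmax / 2.0


def shikata_f3(intensity: np.ndarray, lam2_raw: np.ndarray, sigma: float,
               *, intensity_floor: float = 0.0) -> tuple[np.ndarray, int]:
    """Shikata tubular response σ_r²·λ2 / I from the *raw* eigenvalue.

    Voxels with |I| at or below ``intensity_floor`` get 0; the number of such
    guarded voxels is returned alongside (no hard failure inside volume loops).
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    lam2_raw = np.asarray(lam2_raw, dtype=np.float64)
    low = np.abs(intensity) <= intensity_floor
    n_low = int(np.count_nonzero(low))
    safe = np.where(low, 1.0, intensity)
    return np.where(low, 0.0, sigma * sigma * lam2_raw / safe), n_low


def li_f4(lam1: np.ndarray, lam2: np.ndarray, lam3: np.ndarray) -> np.ndarray:
    """Li tube-selective response λ2(λ2−λ3)/λ1, active when λ1 < 0 and λ2 < 0.

    With the signed ordering λ1 > λ2 > λ3 the active branch is non-negative.
    """
    lam1 = np.asarray(lam1, dtype=np.float64)
    lam2 = np.asarray(lam2, dtype=np.float64)
    lam3 = np.asarray(lam3, dtype=np.float64)
    active = (lam1 < 0) & (lam2 < 0)
    # clamp the denominator away from 0⁻ so the (unbounded) response stays
    # finite when the along-axis eigenvalue vanishes on a perfect tube
    floor = 1e-12 * (np.abs(lam2) + np.abs(lam3))
    safe1 = np.where(active, np.minimum(lam1, -floor), 1.0)
    return np.where(active, lam2 * (lam2 - lam3) / safe1, 0.0)


def manniesing_f5(eigenvalues: np.ndarray, alpha: float = 0.5, beta: float = 0.5,
                  gamma: float = 5.0, c: float = 1e-6) -> np.ndarray:
    """Manniesing diffusion-style vesselness in [0, 1].

    The Frangi product times a smoothness factor exp(−2c²/(|λ2|·λ3²)) on the
    magnitude-ordered eigenvalues; strict λ2 ≥ 0 or λ3 ≥ 0 exclusion. At the
    default c = 10⁻⁶ the extra factor is numerically ≈ 1.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    lam = np.asarray(eigenvalues, dtype=np.float64)
    prod, active = _frangi_product(lam, alpha, beta, gamma)
    m = magnitude_view(lam)
    am2, am3 = np.abs(m[..., 1]), np.abs(m[..., 2])
    denom = am2 * am3 * am3
    safe = np.where(denom > 0, denom, 1.0)
    cfac = np.where(denom > 0, np.exp(-2.0 * c * c / safe), 0.0)
    bright = (lam[..., 1] < 0) & (lam[..., 2] < 0)
    return np.where(bright & active, prod * cfac, 0.0)


def save_feature_field(field: FeatureField, volume: Volume, prefix: str,
                       ext: str = ".nii.gz") -> list[str]:
    """Write a feature field as one volume file per (scale, feature).

    Files are named ``{prefix}_s{scale_index}_f{feature_number}{ext}`` on the
    source volume's grid; returns the written paths.
    """
    from .volume import save_volume

    paths = []
    for s in range(field.values.shape[0]):
        for f in range(field.values.shape[1]):
            path = f"{prefix}_s{s}_f{f + 1}{ext}"
            save_volume(volume.like(field.values[s, f]), path)
            paths.append(path)
    return paths


def multiscale_features(volume: Volume, bank: ScaleBank | None = None,
                        params: FeatureParams | None = None, *,
                        keep_hessian: bool = False,
                        roi: np.ndarray | None = None) -> FeatureField:
    """Compute the five-feature bank at every voxel and scale.

    Returns a :class:`FeatureField` with ``values`` of shape
    ``(n_scales, 5) + volume.shape``, finite everywhere and deterministic.
    An optional boolean ``roi`` restricts the eigen-analysis and feature
    evaluation to a region of interest (values outside are 0); the Gaussian
    smoothing itself is always global, so values inside the ROI are exact.
    """
    bank = bank or default_scale_bank()
    params = params or FeatureParams()
    data = np.asarray(volume.data, dtype=np.float64)
    floor = params.intensity_floor_rel * float(np.abs(data).max())
    values = np.zeros((len(bank), N_FEATURES) + volume.shape, dtype=np.float32)
    hessians = (np.empty((len(bank), 6) + volume.shape, dtype=np.float32)
                if keep_hessian else None)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != volume.shape:
            raise ValueError("roi shape must match the volume")
    n_low = 0
    for si, sigma in enumerate(bank.sigmas):
        comp = hessian_at_scale(volume, sigma)
        if hessians is not None:
            hessians[si] = comp
        if params.frangi_gamma is not None:
            gamma2 = params.frangi_gamma
        else:
            try:
                gamma2 = frangi_gamma(comp)  # over the full field, per scale
            except FeatureComputationError:
                gamma2 = None  # constant image: every feature is 0 anyway
        if roi is not None:
            comp = comp[:, roi]
            intens = data[roi]
        else:
            intens = data
        lam = eigenvalues_analytic(comp)  # (..., 3) signed-descending, normalized
        lam1, lam2, lam3 = lam[..., 0], lam[..., 1], lam[..., 2]
        out = np.zeros((N_FEATURES,) + lam1.shape, dtype=np.float32)
        out[0] = sato_f1(lam1, lam2, params.sato_alpha1, params.sato_alpha2)
        if gamma2 is not None:
            out[1] = frangi_f2(lam, params.frangi_alpha,
                               params.frangi_beta, gamma2)
        # f3 on the raw eigenvalue: σ²·(λ2_norm/σ²)/I = λ2_norm/I.
        f3, nl = shikata_f3(intens, lam2 / (sigma * sigma), sigma,
                            intensity_floor=floor)
        out[2] = f3
        n_low += nl
        out[3] = li_f4(lam1, lam2, lam3)
        out[4] = manniesing_f5(lam, params.manniesing_alpha,
                               params.manniesing_beta,
                               params.manniesing_gamma,
                               params.manniesing_c)
        if roi is not None:
            values[si][:, roi] = out
        else:
            values[si] = out
    if not np.all(np.isfinite(values)):
        raise FeatureComputationError("non-finite feature values computed")
    return FeatureField(values, bank, n_low, hessians)
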
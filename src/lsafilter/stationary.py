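"""Stationary spatial filters: the four fixed-weight comparators.

* Vertex reference (VR): subtract the signal at Cz from every electrode.
* Average reference (AR): subtract the instantaneous mean over electrodes.
* Surface Laplacian (SL): spherical-spline estimate of the second spatial
  derivative (current source density, µV/cm²), after Perrin et al.'s
  spherical-spline interpolation.
* Contralateral difference (CD): subtract from each electrode its mirror
  partner across the sagittal midline.

All four are linear operators with weights fixed a priori — the foil
against which the adaptive LSA filter is compared.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre

from .containers import EpochSet
from .montage import Montage

__all__ = [
    "SplineParams",
    "vertex_reference",
    "average_reference",
    "surface_laplacian",
    "surface_laplacian_transform",
    "contralateral_difference",
]


@dataclass
class SplineParams:
    """Spherical-spline parameters for the surface Laplacian.

    ``smoothing`` is the regularization added to the diagonal of the
    interpolation matrix; ``legendre_terms`` the truncation order of the
    Legendre series defining the spline kernels; ``spline_order`` the
    exponent m of the spline (m = 3 here; m = 4 is the more common
    literature default — both are exposed).
    """

    smoothing: float = 1e-5
    legendre_terms: int = 80
    spline_order: int = 3

    def __post_init__(self) -> None:
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        if self.legendre_terms < 1:
            raise ValueError("legendre_terms must be >= 1")
        if self.spline_order < 2:
            raise ValueError("spline_order must be >= 2")


def vertex_reference(epochs: EpochSet, vertex: str = "Cz") -> EpochSet:
    """Subtract the signal at the vertex electrode from every channel.

    The output at the vertex itself is zero.
    """
    vi = epochs.channel_index(vertex)
    out = epochs.data - epochs.data[:, vi:vi + 1, :]
    result = epochs.copy_with(data=out)
    result.provenance = dict(epochs.provenance,
                             filter={"method": "vr", "vertex": epochs.labels[vi]})
    return result


def average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean over all electrodes from each
    electrode; the output is zero-mean across channels at every trial and
    sample."""
    if epochs.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    result = epochs.copy_with(data=out)
    result.provenance = dict(epochs.provenance, filter={"method": "ar"})
    return result


def contralateral_difference(epochs: EpochSet, montage: Montage) -> EpochSet:
    """Subtract from each electrode its mirror partner across the sagittal
    midline.

    Midline electrodes give exactly zero; the output is antisymmetric
    under mirroring.  Raises if any lateral channel lacks its partner.
    """
    unpaired = []
    perm = np.empty(epochs.n_channels, dtype=int)
    for i, lab in enumerate(epochs.labels):
        try:
            partner = montage.mirror_electrode(lab)
            perm[i] = epochs.channel_index(partner)
        except KeyError:
            unpaired.append(lab)
    if unpaired:
        raise ValueError(
            "no mirror partner in the data for: " + ", ".join(unpaired)
        )
    out = epochs.data - epochs.data[:, perm, :]
    result = epochs.copy_with(data=out)
    result.provenance = dict(epochs.provenance, filter={"method": "cd"})
    return result


def surface_laplacian_transform(montage: Montage, labels: list[str],
                                params: SplineParams | None = None) -> np.ndarray:
    """The channels × channels linear map from a voltage topography to its
    spherical-spline current source density (µV → µV/cm²).

    Builds the spherical-spline interpolation system of Perrin et al.:
    the g kernel ``g(x) = (1/4π) Σ_n (2n+1)/(n(n+1))^m P_n(x)`` (n up to
    ``legendre_terms``, m the spline order), solves for the spline
    coefficients under a zero-sum constraint with ``smoothing`` added to
    the diagonal, and evaluates the Laplacian through the h kernel
    ``h(x) = (1/4π) Σ_n (2n+1)/(n(n+1))^(m-1) P_n(x)`` scaled by the
    inverse squared head radius.  The sign follows the CSD convention: a
    potential peak maps to a CSD extremum of the same sign.
    """
    params = params or SplineParams()
    sub = montage.subset(list(labels))
    n = len(sub.labels)
    if n < 32:
        warnings.warn(
            f"surface Laplacian on only {n} channels; estimates are unreliable "
            "below ~32 channels",
            UserWarning,
            stacklevel=2,
        )
    u = sub.unit_vectors()
    cosang = np.clip(u @ u.T, -1.0, 1.0)

    ns = np.arange(params.legendre_terms + 1, dtype=float)
    with np.errstate(divide="ignore"):
        denom = (ns * (ns + 1.0))
    g_coef = np.zeros_like(ns)
    h_coef = np.zeros_like(ns)
    g_coef[1:] = (2 * ns[1:] + 1) / denom[1:] ** params.spline_order / (4 * np.pi)
    h_coef[1:] = (2 * ns[1:] + 1) / denom[1:] ** (params.spline_order - 1) / (4 * np.pi)
    G = legendre.legval(cosang, g_coef)
    H = legendre.legval(cosang, h_coef)

    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + params.smoothing * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "spherical-spline interpolation system is singular; "
            "try a larger smoothing parameter"
        ) from None
    # coefficient solve restricted to the voltage inputs
    return (H @ Ainv[:n, :n]) / sub.head_radius**2


def surface_laplacian(epochs: EpochSet, montage: Montage,
                      params: SplineParams | None = None) -> EpochSet:
    """Spherical-spline surface Laplacian of every trial and sample.

    Returns current source density in µV/cm² (head radius taken from the
    montage).  Linear in the input; a spatially constant topography maps
    to (numerically) zero.
    """
    missing = [lab for lab in epochs.labels if lab not in montage]
    if missing:
        raise ValueError(
            "montage lacks positions for data channels: " + ", ".join(missing)
        )
    T = surface_laplacian_transform(montage, epochs.labels, params)
    out = np.einsum("dc,kcs->kds", T, epochs.data)
    result = epochs.copy_with(data=out, units="uV/cm^2")
    result.provenance = dict(
        epochs.provenance,
        filter={"method": "sl",
                "params": {"smoothing": (params or SplineParams()).smoothing,
                           "legendre_terms": (params or SplineParams()).legendre_terms,
                           "spline_order": (params or SplineParams()).spline_order}},
    )
    return result
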
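"""Spectral geometry on molecular surfaces.

Builds a Laplacian on either a triangle mesh (cotangent weights with a
lumped mass matrix) or a raw point cloud (kNN Gaussian-weight graph
Laplacian with density-based mass), extracts the low generalized
eigenpairs, and derives from them the Heat Kernel Signature and the
spectral heat-diffusion operator used by the surface diffusion models.

All spectral quantities are intrinsic: they depend only on inter-point
distances, so they are invariant under rigid motions of the molecule and
stable under small shape perturbations — the property that makes them
useful descriptors for binding-site prediction on flexible proteins.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .types import SpectralBasis

__all__ = [
    "HKSConfig",
    "build_laplacian",
    "eigendecompose",
    "compute_hks",
    "heat_diffuse",
    "compute_basis",
    "normalize_surface_area",
]


@dataclass
class HKSConfig:
    """Heat Kernel Signature sampling: log-spaced diffusion times."""

    num_scales: int = 16
    t_min: float = 0.01
    t_max: float = 1.0
    normalize: bool = True  # scale each column to unit mass-weighted mean

    def __post_init__(self) -> None:
        if not (0 < self.t_min < self.t_max):
            raise ValueError("need 0 < t_min < t_max")
        if self.num_scales < 1:
            raise ValueError("num_scales must be >= 1")

    def times(self) -> np.ndarray:
        return np.geomspace(self.t_min, self.t_max, self.num_scales)


def _triangle_areas(points: np.ndarray, faces: np.ndarray) -> np.ndarray:
    a, b, c = points[faces[:, 0]], points[faces[:, 1]], points[faces[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def _cotan_laplacian(
    points: np.ndarray, faces: np.ndarray
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Cotangent stiffness and lumped (barycentric) mass of a mesh."""
    areas = _triangle_areas(points, faces)
    good = areas > 1e-12
    if not np.any(good):
        raise ValueError("all triangles degenerate")
    faces = faces[good]
    areas = areas[good]

    n = len(points)
    rows, cols, vals = [], [], []
    for corner in range(3):
        i = faces[:, corner]
        j = faces[:, (corner + 1) % 3]
        k = faces[:, (corner + 2) % 3]
        # cotangent at the corner opposite edge (j, k)
        u = points[j] - points[i]
        v = points[k] - points[i]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-12)
        w = 0.5 * cot
        rows.extend([j, k])
        cols.extend([k, j])
        vals.extend([-w, -w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sp.coo_matrix((-vals, (rows, cols)), shape=(n, n)).tocsr()
    W = 0.5 * (W + W.T)  # enforce symmetry against float noise
    S = sp.csr_matrix(sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W)

    mass = np.zeros(n)
    for corner in range(3):
        np.add.at(mass, faces[:, corner], areas / 3.0)
    mass = np.maximum(mass, 1e-12 * mass[mass > 0].mean())
    return S, mass


def _pointcloud_laplacian(
    points: np.ndarray, n_neighbors: int = 12
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Symmetric kNN Gaussian-weight graph Laplacian with positive mass.

    Edge weights exp(-d^2 / sigma_i sigma_j) with a per-point bandwidth
    equal to the mean kNN distance; mass is the squared local spacing, a
    surface-area proxy so heat diffusion scales like on a mesh.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    k = min(n_neighbors + 1, n)
    tree = cKDTree(pts)
    d, idx = tree.query(pts, k=k)
    d, idx = d[:, 1:], idx[:, 1:]  # drop the self neighbor
    sigma = np.maximum(d.mean(axis=1), 1e-12)

    rows = np.repeat(np.arange(n), idx.shape[1])
    cols = idx.ravel()
    w = np.exp(-(d.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)  # symmetrize: keep an edge if either endpoint has it
    S = sp.csr_matrix(sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W)
    mass = sigma**2
    return S, mass


def build_laplacian(
    points: np.ndarray, faces: np.ndarray | None = None
) -> tuple[sp.csr_matrix, np.ndarray]:
    """(symmetric PSD stiffness, positive mass vector).

    Mesh inputs get the cotangent Laplacian with barycentric lumped
    mass; a point cloud (``faces`` None or empty) gets the kNN graph
    construction.  In both cases the stiffness is symmetric PSD and its
    rows sum to zero (constants are in the kernel).
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 points")
    if faces is not None and np.asarray(faces).size:
        return _cotan_laplacian(pts, np.asarray(faces, dtype=int))
    return _pointcloud_laplacian(pts)


def _fix_signs(evecs: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first nonzero entry positive."""
    out = evecs.copy()
    for c in range(out.shape[1]):
        col = out[:, c]
        nz = np.flatnonzero(np.abs(col) > 1e-10)
        if nz.size and col[nz[0]] < 0:
            out[:, c] = -col
    return out


def eigendecompose(stiffness: sp.spmatrix, mass: np.ndarray, k: int) -> SpectralBasis:
    """K smallest generalized eigenpairs of ``S phi = lambda M phi``.

    Eigenvalues ascending (first ~0 for a connected surface); the
    eigenvectors are mass-orthonormal with a deterministic sign so cached
    bases are reproducible.
    """
    n = stiffness.shape[0]
    if k > n - 1:
        raise ValueError(f"k={k} must be <= P-1={n - 1}")
    A = stiffness.tocsc()
    M = sp.diags(np.asarray(mass, dtype=float))
    if k >= n - 1 or n <= 200:
        # dense route for small problems: no convergence concerns
        evals, evecs = _dense_eig(A.toarray(), np.asarray(mass))
        evals, evecs = evals[:k], evecs[:, :k]
    else:
        try:
            evals, evecs = spla.eigsh(A, k=k, M=M, sigma=-1e-8, which="LM")
        except Exception:
            # retry with a different shift before giving up
            evals, evecs = spla.eigsh(
                A + 1e-8 * M, k=k, M=M, sigma=-1e-6, which="LM"
            )
            evals = evals - 1e-8
    order = np.argsort(evals)
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    # re-normalize in the mass inner product and fix signs
    norms = np.sqrt(np.einsum("pk,p,pk->k", evecs, mass, evecs))
    evecs = evecs / norms
    return SpectralBasis(evals=evals, evecs=_fix_signs(evecs), mass=np.asarray(mass))


def _dense_eig(A: np.ndarray, mass: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from scipy.linalg import eigh

    evals, evecs = eigh(A, np.diag(mass))
    return evals, evecs


def compute_hks(basis: SpectralBasis, config: HKSConfig | None = None) -> np.ndarray:
    """Heat Kernel Signature: hks(p, t) = sum_i exp(-lambda_i t) phi_i(p)^2.

    Columns are the log-spaced diffusion times of ``config``; with
    ``config.normalize`` each column is scaled to unit mass-weighted
    mean, making signatures comparable across surfaces.
    """
    config = config or HKSConfig()
    times = config.times()
    phi2 = basis.evecs**2  # (P, K)
    decay = np.exp(-np.outer(basis.evals, times))  # (K, T)
    hks = phi2 @ decay  # (P, T)
    if config.normalize:
        total_mass = basis.mass.sum()
        col_mean = (basis.mass @ hks) / total_mass
        hks = hks / np.maximum(col_mean, 1e-300)
    return hks


def heat_diffuse(
    basis: SpectralBasis, signal: np.ndarray, times: np.ndarray | float
) -> np.ndarray:
    """Diffuse each signal channel for its own time in the eigenbasis.

    out_c = Phi diag(exp(-lambda t_c)) Phi^T M signal_c.  At t=0 this is
    the K-band-limited projection of the signal; as t grows every channel
    tends to its mass-weighted mean (total heat is conserved).
    """
    sig = np.atleast_2d(np.asarray(signal, dtype=float).T).T  # (P, C)
    t = np.broadcast_to(np.asarray(times, dtype=float), (sig.shape[1],))
    if np.any(t < 0):
        raise ValueError("diffusion times must be nonnegative")
    coeff = basis.evecs.T @ (basis.mass[:, None] * sig)  # (K, C)
    coeff = coeff * np.exp(-np.outer(basis.evals, t))  # (K, C)
    out = basis.evecs @ coeff
    return out.reshape(np.shape(signal))


def normalize_surface_area(points: np.ndarray, mass: np.ndarray) -> float:
    """Scale factor that normalizes total surface area (mass) to one.

    Applying ``points * s`` with ``s = 1/sqrt(total_mass)`` rescales the
    Laplacian spectrum so HKS time ranges are comparable across proteins
    of different sizes.
    """
    return 1.0 / np.sqrt(mass.sum())


def compute_basis(
    points: np.ndarray,
    faces: np.ndarray | None = None,
    k: int = 128,
    area_normalize: bool = True,
) -> SpectralBasis:
    """Laplacian eigenbasis of a surface, truncated to ``k`` pairs.

    With ``area_normalize`` the geometry is rescaled to unit total area
    first, so diffusion times and HKS scales mean the same thing on
    small and large molecules.
    """
    pts = np.asarray(points, dtype=float)
    k = min(k, pts.shape[0] - 1)
    S, mass = build_laplacian(pts, faces)
    if area_normalize:
        s = normalize_surface_area(pts, mass)
        S2, mass2 = build_laplacian(pts * s, faces)
        return eigendecompose(S2, mass2, k)
    return eigendecompose(S, mass, k)
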
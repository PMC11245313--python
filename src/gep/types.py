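"""Shared domain types for antibody-antigen binding-site prediction.

The pipeline represents each protein of a complex twice: as a residue
interaction graph (inner structure) and as a sampled molecular surface
(outer structure).  Both views are derived from the same parsed PDB
coordinates, so residue indexing is consistent across them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: residue identity as it appears in the source PDB: (chain id, resseq, icode)
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class Atom:
    """A single atom with its owning residue key. Coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray  # shape (3,)
    residue_key: ResidueKey

    def __post_init__(self) -> None:
        c = np.asarray(self.coord, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.name}: coordinate must be 3 finite floats")
        object.__setattr__(self, "coord", c)


@dataclass
class ProteinStructure:
    """Parsed chains/residues/atoms of one molecule (antibody or antigen).

    ``residues`` holds ``(residue_key, aa3, (start, stop))`` where the
    half-open atom index range points into ``atoms``. Residues follow
    chain order, then sequence number, then insertion code.
    """

    chains: list[str]
    residues: list[tuple[ResidueKey, str, tuple[int, int]]]
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("structure must contain at least one residue")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def atom_coords(self) -> np.ndarray:
        """All atom coordinates as an (A, 3) array."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def atom_residue_index(self) -> np.ndarray:
        """For every atom, the index of its owning residue."""
        idx = np.empty(len(self.atoms), dtype=int)
        for r, (_, _, (lo, hi)) in enumerate(self.residues):
            idx[lo:hi] = r
        return idx

    def residue_atoms(self, r: int) -> list[Atom]:
        lo, hi = self.residues[r][2]
        return self.atoms[lo:hi]

    def residue_keys(self) -> list[ResidueKey]:
        return [k for k, _, _ in self.residues]


@dataclass
class ResidueGraph:
    """Residue-level proximity graph: the inner-structure representation."""

    node_coords: np.ndarray  # (R, 3)
    node_features: np.ndarray  # (R, 28)
    edges: np.ndarray  # (E, 2) directed pairs
    residue_keys: list[ResidueKey]

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]


@dataclass
class SurfaceBundle:
    """Sampled molecular surface with per-point features: the outer view."""

    points: np.ndarray  # (P, 3)
    faces: np.ndarray  # (T, 3) or empty
    point_features: np.ndarray  # (P, F)
    point_to_residue: np.ndarray  # (P,) int

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class BindingLabels:
    """Per-residue binary interface labels for one molecule."""

    per_residue: np.ndarray  # (R,) bool

    @property
    def positive_count(self) -> int:
        return int(np.count_nonzero(self.per_residue))


@dataclass
class SpectralBasis:
    """Truncated Laplacian eigenbasis of one surface.

    ``evals`` ascending and nonnegative; ``evecs`` mass-orthonormal,
    i.e. evecs.T @ diag(mass) @ evecs = I.
    """

    evals: np.ndarray  # (K,)
    evecs: np.ndarray  # (P, K)
    mass: np.ndarray  # (P,)


@dataclass
class ComplexSample:
    """One antibody-antigen pair: the unit of training and evaluation."""

    sample_id: str
    ab_structure: ProteinStructure
    ag_structure: ProteinStructure
    ab_graph: ResidueGraph
    ag_graph: ResidueGraph
    ab_surface: SurfaceBundle
    ag_surface: SurfaceBundle
    ab_labels: BindingLabels
    ag_labels: BindingLabels
    cdr_mask: np.ndarray  # (R_ab,) bool; all-true when no CDR spec given
    ab_basis: SpectralBasis | None = None
    ag_basis: SpectralBasis | None = None
    ab_hks: np.ndarray | None = None  # (P_ab, n_scales)
    ag_hks: np.ndarray | None = None


@dataclass
class ManifestEntry:
    complex_id: str
    antibody_chains: list[str]
    antigen_chains: list[str]
    split: str  # "train" | "val" | "test"
    structure_path: str | None = None
    mesh_paths: dict[str, str] = field(default_factory=dict)


@dataclass
class ComplexManifest:
    """List of complexes with chain assignments and split membership."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.complex_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("complex ids in a manifest must be unique")
        for e in self.entries:
            if set(e.antibody_chains) & set(e.antigen_chains):
                raise ValueError(
                    f"{e.complex_id}: antibody and antigen chain sets overlap"
                )

    def split_ids(self, split: str) -> list[str]:
        return [e.complex_id for e in self.entries if e.split == split]
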
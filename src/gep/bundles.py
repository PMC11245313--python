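"""On-disk bundle cache: one file per complex holding both representations.

Graph- and surface-based models consume identical inputs because both
views of a complex (residue graph, sampled surface, spectral basis,
HKS, labels) live in a single versioned ``.npz`` bundle.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .types import (
    Atom,
    BindingLabels,
    ComplexSample,
    ProteinStructure,
    ResidueGraph,
    SpectralBasis,
    SurfaceBundle,
)

SCHEMA_VERSION = "gep-bundle-1"

__all__ = ["save_bundle", "load_bundle", "SCHEMA_VERSION"]


def _pack_structure(prefix: str, s: ProteinStructure, out: dict) -> None:
    out[f"{prefix}_chains"] = np.array(s.chains)
    out[f"{prefix}_res_keys"] = np.array(
        [[k[0], str(k[1]), k[2]] for k, _, _ in s.residues]
    )
    out[f"{prefix}_res_aa"] = np.array([aa for _, aa, _ in s.residues])
    out[f"{prefix}_res_range"] = np.array([rng for _, _, rng in s.residues], dtype=int)
    out[f"{prefix}_atom_names"] = np.array([a.name for a in s.atoms])
    out[f"{prefix}_atom_elements"] = np.array([a.element for a in s.atoms])
    out[f"{prefix}_atom_coords"] = s.atom_coords()


def _unpack_structure(prefix: str, z) -> ProteinStructure:
    keys = z[f"{prefix}_res_keys"]
    aas = z[f"{prefix}_res_aa"]
    ranges = z[f"{prefix}_res_range"]
    names = z[f"{prefix}_atom_names"]
    elements = z[f"{prefix}_atom_elements"]
    coords = z[f"{prefix}_atom_coords"]
    residues = []
    atoms: list[Atom] = []
    for (chain, resseq, icode), aa, (lo, hi) in zip(keys, aas, ranges):
        key = (str(chain), int(resseq), str(icode))
        for i in range(lo, hi):
            atoms.append(
                Atom(
                    name=str(names[i]),
                    element=str(elements[i]),
                    coord=coords[i],
                    residue_key=key,
                )
            )
        residues.append((key, str(aa), (int(lo), int(hi))))
    return ProteinStructure(
        chains=[str(c) for c in z[f"{prefix}_chains"]], residues=residues, atoms=atoms
    )


def save_bundle(sample: ComplexSample, path: str | Path) -> None:
    out: dict = {"schema": np.array(SCHEMA_VERSION), "sample_id": np.array(sample.sample_id)}
    _pack_structure("ab", sample.ab_structure, out)
    _pack_structure("ag", sample.ag_structure, out)
    for prefix, graph in (("ab", sample.ab_graph), ("ag", sample.ag_graph)):
        out[f"{prefix}_node_coords"] = graph.node_coords
        out[f"{prefix}_node_features"] = graph.node_features
        out[f"{prefix}_edges"] = graph.edges
    for prefix, surf in (("ab", sample.ab_surface), ("ag", sample.ag_surface)):
        out[f"{prefix}_points"] = surf.points
        out[f"{prefix}_faces"] = surf.faces
        out[f"{prefix}_point_features"] = surf.point_features
        out[f"{prefix}_p2r"] = surf.point_to_residue
    out["ab_labels"] = sample.ab_labels.per_residue
    out["ag_labels"] = sample.ag_labels.per_residue
    out["cdr_mask"] = sample.cdr_mask
    for prefix, basis in (("ab", sample.ab_basis), ("ag", sample.ag_basis)):
        if basis is not None:
            out[f"{prefix}_evals"] = basis.evals
            out[f"{prefix}_evecs"] = basis.evecs
            out[f"{prefix}_mass"] = basis.mass
    if sample.ab_hks is not None:
        out["ab_hks"] = sample.ab_hks
    if sample.ag_hks is not None:
        out["ag_hks"] = sample.ag_hks
    np.savez_compressed(path, **out)


def load_bundle(path: str | Path) -> ComplexSample:
    z = np.load(path, allow_pickle=False)
    schema = str(z["schema"])
    if schema != SCHEMA_VERSION:
        raise ValueError(f"unsupported bundle schema {schema!r} (expected {SCHEMA_VERSION})")
    ab_s = _unpack_structure("ab", z)
    ag_s = _unpack_structure("ag", z)

    def graph(prefix, s):
        return ResidueGraph(
            node_coords=z[f"{prefix}_node_coords"],
            node_features=z[f"{prefix}_node_features"],
            edges=z[f"{prefix}_edges"].astype(int),
            residue_keys=s.residue_keys(),
        )

    def surface(prefix):
        return SurfaceBundle(
            points=z[f"{prefix}_points"],
            faces=z[f"{prefix}_faces"].astype(int),
            point_features=z[f"{prefix}_point_features"],
            point_to_residue=z[f"{prefix}_p2r"].astype(int),
        )

    def basis(prefix):
        if f"{prefix}_evals" not in z:
            return None
        return SpectralBasis(
            evals=z[f"{prefix}_evals"], evecs=z[f"{prefix}_evecs"], mass=z[f"{prefix}_mass"]
        )

    return ComplexSample(
        sample_id=str(z["sample_id"]),
        ab_structure=ab_s,
        ag_structure=ag_s,
        ab_graph=graph("ab", ab_s),
        ag_graph=graph("ag", ag_s),
        ab_surface=surface("ab"),
        ag_surface=surface("ag"),
        ab_labels=BindingLabels(per_residue=z["ab_labels"].astype(bool)),
        ag_labels=BindingLabels(per_residue=z["ag_labels"].astype(bool)),
        cdr_mask=z["cdr_mask"].astype(bool),
        ab_basis=basis("ab"),
        ag_basis=basis("ag"),
        ab_hks=z["ab_hks"] if "ab_hks" in z else None,
        ag_hks=z["ag_hks"] if "ag_hks" in z else None,
    )
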
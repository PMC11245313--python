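"""Reading and writing the standard formats the pipeline touches.

PDB structures are parsed with Biopython, surface meshes with trimesh;
per-residue predictions are written as plain TSV so downstream tools can
consume them without this package.
"""
from __future__ import annotations

import io as _io
import json
import warnings
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .types import (
    Atom,
    ComplexManifest,
    ManifestEntry,
    ProteinStructure,
    ResidueKey,
)

__all__ = [
    "parse_structure",
    "load_surface",
    "write_predictions",
    "read_predictions",
    "load_manifest",
    "save_manifest",
]

#: standard 3-letter amino-acid codes; anything else is "unclassified"
STANDARD_AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


class EmptySelectionError(ValueError):
    """None of the requested chains produced any residues."""


class PDBFormatError(ValueError):
    """Malformed PDB content."""


class MeshFormatError(ValueError):
    """Malformed or inconsistent surface mesh file."""


def _pick_highest_occupancy(atom):
    """Resolve alternate locations to the highest-occupancy conformer."""
    if not atom.is_disordered():
        return atom
    best, best_occ = None, -np.inf
    for child in atom.disordered_get_list():
        occ = child.get_occupancy()
        occ = 1.0 if occ is None else float(occ)
        if occ > best_occ:
            best, best_occ = child, occ
    return best


def parse_structure(pdb_text: str, chain_ids: set[str]) -> ProteinStructure:
    """Parse PDB-format text, keeping only the requested chains.

    Heteroatoms and waters are dropped; only standard ``ATOM`` records
    form residues.  Alternate locations resolve to the highest-occupancy
    conformer (missing occupancy counts as 1.0).  Multi-model files use
    the first model only.

    Parameters
    ----------
    pdb_text : str
        Content of a PDB file.
    chain_ids : set of str
        Chains to retain; must be nonempty.

    Raises
    ------
    EmptySelectionError
        If no requested chain contributes residues.
    PDBFormatError
        If an ATOM record cannot be parsed (message carries the line).
    """
    if not chain_ids:
        raise ValueError("chain_ids must be nonempty")
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            model = next(iter(parser.get_structure("s", _io.StringIO(pdb_text))))
    except (PDBConstructionException, ValueError) as exc:
        raise PDBFormatError(f"malformed PDB record: {exc}") from exc

    chains_seen: list[str] = []
    residues: list[tuple[ResidueKey, str, tuple[int, int]]] = []
    atoms: list[Atom] = []
    for chain in model:
        cid = chain.id
        if cid not in chain_ids:
            continue
        chain_has_residue = False
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag != " ":  # heteroatoms and waters excluded
                continue
            key: ResidueKey = (cid, int(resseq), icode.strip() or "")
            lo = len(atoms)
            for atom in res:
                atom = _pick_highest_occupancy(atom)
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        element=(atom.element or "").strip() or atom.get_name()[:1],
                        coord=np.asarray(atom.get_coord(), dtype=float),
                        residue_key=key,
                    )
                )
            if len(atoms) == lo:
                continue
            residues.append((key, res.get_resname().strip(), (lo, len(atoms))))
            chain_has_residue = True
        if chain_has_residue:
            chains_seen.append(cid)

    if not residues:
        raise EmptySelectionError(
            f"no residues found for chains {sorted(chain_ids)}"
        )
    return ProteinStructure(chains=chains_seen, residues=residues, atoms=atoms)


def load_surface(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a surface mesh or point cloud from an OFF or PLY file.

    Returns
    -------
    vertices : (N, 3) float array, Angstrom
    faces : (T, 3) int array; empty for a pure point cloud
    """
    import trimesh

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        loaded = trimesh.load(str(path), process=False)
    except Exception as exc:  # trimesh raises assorted types on bad files
        raise MeshFormatError(f"{path}: {exc}") from exc

    if isinstance(loaded, trimesh.points.PointCloud):
        vertices = np.asarray(loaded.vertices, dtype=float)
        faces = np.empty((0, 3), dtype=int)
    else:
        vertices = np.asarray(loaded.vertices, dtype=float)
        faces = np.asarray(loaded.faces, dtype=int).reshape(-1, 3)
    if vertices.size == 0:
        raise MeshFormatError(f"{path}: no vertices")
    if not np.all(np.isfinite(vertices)):
        raise MeshFormatError(f"{path}: non-finite vertex coordinates")
    if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
        raise MeshFormatError(
            f"{path}: face index out of range (max {faces.max()}, "
            f"{len(vertices)} vertices)"
        )
    return vertices, faces


def to_pdb_text(structure: ProteinStructure) -> str:
    """Serialize a structure back to minimal PDB ATOM records."""
    lines = []
    serial = 1
    for key, aa3, (lo, hi) in structure.residues:
        chain, resseq, icode = key
        for atom in structure.atoms[lo:hi]:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            x, y, z = atom.coord
            lines.append(
                f"ATOM  {serial:5d} {name:<4.4s} {aa3:<3s} {chain:1.1s}"
                f"{resseq:4d}{icode or ' ':1.1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom.element:>2.2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


_PRED_HEADER = "chain\tresseq\ticode\tamino_acid\tprobability"


def write_predictions(
    sample_id: str,
    per_residue_probs: dict[ResidueKey, float],
    structure: ProteinStructure,
    path: str | Path,
) -> None:
    """Write per-residue binding probabilities as TSV, one row per residue.

    Rows follow the structure's residue order; probabilities are printed
    with six decimal places. Residues absent from the map are skipped.
    """
    lines = [f"# sample: {sample_id}", _PRED_HEADER]
    for key, aa3, _ in structure.residues:
        if key not in per_residue_probs:
            continue
        p = float(per_residue_probs[key])
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} for residue {key} outside [0, 1]")
        chain, resseq, icode = key
        lines.append(f"{chain}\t{resseq}\t{icode or '-'}\t{aa3}\t{p:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_predictions(path: str | Path) -> dict[ResidueKey, float]:
    """Read a prediction TSV written by :func:`write_predictions`."""
    out: dict[ResidueKey, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("chain\t"):
            continue
        chain, resseq, icode, _aa, prob = line.split("\t")
        out[(chain, int(resseq), "" if icode == "-" else icode)] = float(prob)
    return out


def load_manifest(path: str | Path) -> ComplexManifest:
    """Load a complex manifest from JSON."""
    raw = json.loads(Path(path).read_text())
    entries = [
        ManifestEntry(
            complex_id=e["complex_id"],
            antibody_chains=list(e["antibody_chains"]),
            antigen_chains=list(e["antigen_chains"]),
            split=e.get("split", "train"),
            structure_path=e.get("structure_path"),
            mesh_paths=dict(e.get("mesh_paths", {})),
        )
        for e in raw["entries"]
    ]
    return ComplexManifest(entries=entries)


def save_manifest(manifest: ComplexManifest, path: str | Path) -> None:
    payload = {
        "entries": [
            {
                "complex_id": e.complex_id,
                "antibody_chains": e.antibody_chains,
                "antigen_chains": e.antigen_chains,
                "split": e.split,
                "structure_path": e.structure_path,
                "mesh_paths": e.mesh_paths,
            }
            for e in manifest.entries
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))
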
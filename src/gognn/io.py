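"""File formats: molecules (JSON lines), edge/pair/prediction TSV, checkpoints.

Native formats are diffable text: one JSON object per molecule
(``{id, atoms:[{element,valence,h,aromatic}], bonds:[[k,m],...]}``, degrees
derived at load) and two/three-column TSV files with ``#`` comments.  An
optional SDF/SMILES adapter (requires rdkit) maps chemistry files onto the
same structures.  Checkpoints are ``.npz`` archives carrying a JSON header
(format version, config snapshot) plus every trainable array; loading into a
model of a different dimension fails fast.
"""

from __future__ import annotations

import json
import logging
import zipfile
from pathlib import Path

import numpy as np

from .gog import (
    AtomSignature,
    DEFAULT_MAX_ATOMS,
    GoG,
    InternalGraph,
    LinkDataset,
    build_gog,
)

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


class ParseError(ValueError):
    pass


class CheckpointError(ValueError):
    pass


# ---------------------------------------------------------------- molecules
def molecule_to_record(graph: InternalGraph) -> dict:
    return {
        "id": graph.graph_id,
        "atoms": [
            {
                "element": a.element,
                "valence": a.valence,
                "h": a.hydrogen_count,
                "aromatic": a.aromatic,
            }
            for a in graph.atoms
        ],
        "bonds": graph.edge_list(),
    }


def molecule_from_record(rec: dict) -> InternalGraph:
    atoms_raw = rec["atoms"]
    adjacency: list[list[int]] = [[] for _ in atoms_raw]
    for k, m in rec["bonds"]:
        adjacency[k].append(m)
        adjacency[m].append(k)
    atoms = [
        AtomSignature(
            element=a["element"],
            valence=int(a["valence"]),
            hydrogen_count=int(a["h"]),
            degree=len(adjacency[i]),
            aromatic=bool(a.get("aromatic", False)),
        )
        for i, a in enumerate(atoms_raw)
    ]
    return InternalGraph(graph_id=str(rec["id"]), atoms=atoms, adjacency=[sorted(x) for x in adjacency])


def write_molecules(graphs: list[InternalGraph], path) -> None:
    with open(path, "w") as fh:
        for g in graphs:
            fh.write(json.dumps(molecule_to_record(g)) + "\n")


def read_molecules(path, max_atoms: int = DEFAULT_MAX_ATOMS) -> list[InternalGraph]:
    """Parse molecules, skipping (and logging) those over the atom cap."""
    out, skipped = [], 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rec = json.loads(line)
                mol = molecule_from_record(rec)
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if mol.n_atoms > max_atoms:
                skipped += 1
                continue
            out.append(mol)
    if skipped:
        logger.info("skipped %d molecules over the %d-atom cap", skipped, max_atoms)
    return out


# ---------------------------------------------------------------- TSV files
def read_edge_tsv(path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated ids")
            edges.append((fields[0], fields[1]))
    return edges


def write_edge_tsv(edges: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_pairs_tsv(path, gog: GoG, role: str = "train") -> LinkDataset:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected id_i, id_j, label")
            try:
                i = gog.id_index[fields[0]]
                j = gog.id_index[fields[1]]
            except KeyError as exc:
                raise ParseError(f"{path}:{lineno}: unknown compound id {exc}") from exc
            pairs.append((i, j, int(fields[2])))
    return LinkDataset(pairs=pairs, role=role)


def write_pairs_tsv(dataset: LinkDataset, gog: GoG, path) -> None:
    ids = [c.graph_id for c in gog.compounds]
    with open(path, "w") as fh:
        for i, j, t in dataset.pairs:
            fh.write(f"{ids[i]}\t{ids[j]}\t{t}\n")


def write_predictions_tsv(pairs, scores, gog: GoG, path) -> None:
    ids = [c.graph_id for c in gog.compounds]
    with open(path, "w") as fh:
        for (i, j), s in zip(pairs, scores):
            fh.write(f"{ids[i]}\t{ids[j]}\t{s:.10g}\n")


def load_gog(molecules_path, edges_path, max_atoms: int = DEFAULT_MAX_ATOMS) -> GoG:
    """Read molecules + external edge list into a validated GoG."""
    mols = read_molecules(molecules_path, max_atoms=max_atoms)
    edges = read_edge_tsv(edges_path)
    return build_gog(mols, edges)


# ---------------------------------------------------------------- checkpoint
def save_checkpoint(model, path, config: dict | None = None) -> None:
    """Serialize every trainable tensor plus a JSON header to ``.npz``."""
    header = {
        "format_version": CHECKPOINT_VERSION,
        "mode": model.mode,
        "dim": model.dim,
        "config": config or {},
        "atom_signatures": (
            [s.key() for s in model.table.signatures()] if model.table is not None else None
        ),
    }
    arrays = {f"tensor/{k}": v for k, v in model.state_arrays().items()}
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, model) -> dict:
    """Restore tensors into an architecture-compatible model; returns header."""
    try:
        with np.load(path) as npz:
            header = json.loads(bytes(npz["header"]).decode())
            arrays = {k[len("tensor/"):]: npz[k] for k in npz.files if k.startswith("tensor/")}
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as exc:
        raise CheckpointError(f"corrupted or unreadable checkpoint {path}: {exc}") from exc
    if header.get("format_version") != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint format {header.get('format_version')} != {CHECKPOINT_VERSION}"
        )
    if header["dim"] != model.dim:
        raise CheckpointError(f"checkpoint d={header['dim']} incompatible with model d={model.dim}")
    if header["mode"] != model.mode:
        raise CheckpointError(f"checkpoint mode {header['mode']!r} != model mode {model.mode!r}")
    try:
        model.load_state_arrays(arrays)
    except (KeyError, ValueError) as exc:
        raise CheckpointError(str(exc)) from exc
    return header


# ---------------------------------------------------------------- chemistry
def molecules_from_sdf(path, max_atoms: int = DEFAULT_MAX_ATOMS) -> list[InternalGraph]:
    """Optional adapter: read an SDF file into internal graphs (needs rdkit).

    Hydrogens become signature counts, bond orders are dropped, and
    valence/aromaticity are taken as perceived by the toolkit.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("the SDF adapter requires rdkit (install extra 'chem')") from exc
    out, skipped = [], 0
    for idx, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        mol = Chem.RemoveHs(mol)
        if mol.GetNumAtoms() > max_atoms:
            skipped += 1
            continue
        adjacency: list[list[int]] = [[] for _ in range(mol.GetNumAtoms())]
        for bond in mol.GetBonds():
            a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            adjacency[a].append(b)
            adjacency[b].append(a)
        atoms = [
            AtomSignature(
                element=at.GetSymbol(),
                valence=at.GetTotalValence(),
                hydrogen_count=at.GetTotalNumHs(),
                degree=len(adjacency[at.GetIdx()]),
                aromatic=at.GetIsAromatic(),
            )
            for at in mol.GetAtoms()
        ]
        name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{idx}"
        out.append(InternalGraph(graph_id=name, atoms=atoms, adjacency=[sorted(x) for x in adjacency]))
    if skipped:
        logger.info("skipped %d SDF molecules over the %d-atom cap", skipped, max_atoms)
    return out
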
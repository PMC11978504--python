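"""Read protein structures plus nonprotein context atoms; write design artifacts.

Parsing is backed by biotite's PDB/PDBx readers. Standard and nonstandard
amino-acid residues populate :class:`ProteinStructure`; every other residue
(minus a configurable exclusion list, by default ``['HOH','NA','CL','K','BR']``)
becomes part of :class:`ContextAtoms`. Sidechain heavy atoms of protein
residues are also exposed as optional context (category ``PROTEIN_SIDECHAIN``)
so they can be donated as atomic context during training augmentation.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io import pdb as _pdb
from biotite.structure.io import pdbx as _pdbx
from biotite.sequence.io import fasta as _fasta

from .alphabet import THREE_TO_TOKEN, TOKEN_TO_THREE, UNKNOWN_TOKEN, decode_sequence
from .elements import (METAL_SYMBOLS, NUMBER_TO_SYMBOL, atomic_number,
                       infer_element_from_atom_name)

DEFAULT_EXCLUDED_RESIDUES = ("HOH", "NA", "CL", "K", "BR")

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_NUCLEOTIDE_NAMES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}


class StructureError(ValueError):
    """Raised for unreadable files or structures without protein residues."""


class Category(enum.IntEnum):
    SMALL_MOLECULE = 0
    NUCLEOTIDE = 1
    METAL = 2
    PROTEIN_SIDECHAIN = 3


@dataclass(eq=False)
class ProteinStructure:
    """Backbone-level protein representation.

    ``backbone_coords`` is [L, 4, 3] in N/CA/C/O order (Angstrom);
    ``residue_mask`` is True only where all four backbone atoms are present.
    """

    backbone_coords: np.ndarray
    residue_index: np.ndarray
    chain_labels: np.ndarray
    sequence: np.ndarray
    residue_mask: np.ndarray
    chain_ids: tuple[str, ...] = ()

    def __post_init__(self):
        self.backbone_coords = np.asarray(self.backbone_coords, dtype=np.float64)
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.chain_labels = np.asarray(self.chain_labels, dtype=np.int64)
        self.sequence = np.asarray(self.sequence, dtype=np.int64)
        self.residue_mask = np.asarray(self.residue_mask, dtype=bool)

    def __len__(self) -> int:
        return self.backbone_coords.shape[0]

    def copy(self) -> "ProteinStructure":
        return ProteinStructure(self.backbone_coords.copy(), self.residue_index.copy(),
                                self.chain_labels.copy(), self.sequence.copy(),
                                self.residue_mask.copy(), self.chain_ids)


@dataclass(eq=False)
class ContextAtoms:
    """Nonprotein (or donated sidechain) atoms conditioning the design.

    ``residue_of`` maps protein-sidechain atoms to their residue row (-1 for
    nonprotein atoms); ``mol_id`` groups atoms belonging to one molecule.
    """

    coords: np.ndarray
    element: np.ndarray
    category: np.ndarray
    residue_of: np.ndarray = field(default=None)  # type: ignore[assignment]
    mol_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        n = self.coords.shape[0]
        self.element = np.asarray(self.element, dtype=np.int64).reshape(n)
        self.category = np.asarray(self.category, dtype=np.int64).reshape(n)
        if self.residue_of is None:
            self.residue_of = np.full(n, -1, dtype=np.int64)
        self.residue_of = np.asarray(self.residue_of, dtype=np.int64).reshape(n)
        if self.mol_id is None:
            self.mol_id = np.zeros(n, dtype=np.int64)
        self.mol_id = np.asarray(self.mol_id, dtype=np.int64).reshape(n)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def empty(cls) -> "ContextAtoms":
        return cls(np.zeros((0, 3)), np.zeros(0, dtype=np.int64),
                   np.zeros(0, dtype=np.int64))

    def subset(self, mask: np.ndarray) -> "ContextAtoms":
        mask = np.asarray(mask, dtype=bool)
        return ContextAtoms(self.coords[mask], self.element[mask],
                            self.category[mask], self.residue_of[mask],
                            self.mol_id[mask])

    def without_sidechains(self) -> "ContextAtoms":
        return self.subset(self.category != int(Category.PROTEIN_SIDECHAIN))

    @staticmethod
    def concatenate(parts: list["ContextAtoms"]) -> "ContextAtoms":
        parts = [p for p in parts if len(p) > 0]
        if not parts:
            return ContextAtoms.empty()
        offset, mol_ids = 0, []
        for p in parts:
            mol_ids.append(p.mol_id + offset)
            offset += int(p.mol_id.max(initial=-1)) + 1
        return ContextAtoms(
            np.concatenate([p.coords for p in parts]),
            np.concatenate([p.element for p in parts]),
            np.concatenate([p.category for p in parts]),
            np.concatenate([p.residue_of for p in parts]),
            np.concatenate(mol_ids),
        )


def _read_atom_array(path: Path, format: str | None) -> struc.AtomArray:
    if format is None:
        suffix = path.suffix.lower()
        format = "mmcif" if suffix in (".cif", ".mmcif") else "pdb"
    try:
        if format == "pdb":
            pdb_file = _pdb.PDBFile.read(str(path))
            array = _pdb.get_structure(pdb_file, model=1, altloc="occupancy")
        elif format == "mmcif":
            cif_file = _pdbx.CIFFile.read(str(path))
            array = _pdbx.get_structure(cif_file, model=1, altloc="occupancy")
        else:
            raise StructureError(f"unknown format: {format}")
    except StructureError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap reader-specific errors
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    return array


def _atom_elements(array: struc.AtomArray, idx: np.ndarray) -> np.ndarray:
    out = np.zeros(len(idx), dtype=np.int64)
    for j, i in enumerate(idx):
        symbol = array.element[i].strip()
        if symbol:
            out[j] = atomic_number(symbol)
        else:
            out[j] = infer_element_from_atom_name(array.atom_name[i])
    return out


def parse_structure(
    path,
    format: str | None = None,
    excluded_residues: tuple[str, ...] = DEFAULT_EXCLUDED_RESIDUES,
) -> tuple[ProteinStructure, ContextAtoms]:
    """Parse a PDB/mmCIF file into a backbone structure and context atoms.

    Raises :class:`StructureError` for unreadable files or when no protein
    residues are found.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    array = _read_atom_array(path, format)
    array = array[array.element != "H"]
    array = array[array.element != "D"]

    is_protein = struc.filter_amino_acids(array)
    is_nucleotide = struc.filter_nucleotides(array)
    starts = struc.get_residue_starts(array, add_exclusive_stop=True)
    excluded = {name.upper() for name in excluded_residues}

    chain_order: list[str] = []
    bb_coords, res_index, chain_labels, seq, res_mask = [], [], [], [], []
    sc_coords, sc_elements, sc_residue_of = [], [], []
    ctx_coords, ctx_elements, ctx_category, ctx_mol = [], [], [], []
    last_index_per_chain: dict[str, int] = {}
    mol_counter = 0

    for lo, hi in zip(starts[:-1], starts[1:]):
        res_name = array.res_name[lo].upper()
        chain_id = str(array.chain_id[lo])
        idx = np.arange(lo, hi)
        if is_protein[lo]:
            row = len(bb_coords)
            names = [array.atom_name[i] for i in idx]
            coords = np.zeros((4, 3))
            present = np.zeros(4, dtype=bool)
            sidechain_idx = []
            for local, i in enumerate(idx):
                name = names[local]
                if name in BACKBONE_ATOMS:
                    k = BACKBONE_ATOMS.index(name)
                    if not present[k]:
                        coords[k] = array.coord[i]
                        present[k] = True
                elif name != "OXT":
                    sidechain_idx.append(i)
            if chain_id not in chain_order:
                chain_order.append(chain_id)
            # flatten author numbering + insertion codes to a strictly
            # increasing per-chain index
            auth = int(array.res_id[lo])
            prev = last_index_per_chain.get(chain_id)
            flat = auth if (prev is None or auth > prev) else prev + 1
            last_index_per_chain[chain_id] = flat

            bb_coords.append(coords)
            res_index.append(flat)
            chain_labels.append(chain_order.index(chain_id))
            seq.append(THREE_TO_TOKEN.get(res_name, UNKNOWN_TOKEN))
            res_mask.append(bool(present.all()))
            if sidechain_idx:
                sidechain_idx = np.array(sidechain_idx)
                sc_coords.append(array.coord[sidechain_idx])
                sc_elements.append(_atom_elements(array, sidechain_idx))
                sc_residue_of.append(np.full(len(sidechain_idx), row))
        else:
            if res_name in excluded:
                continue
            elements = _atom_elements(array, idx)
            if len(idx) == 1 and NUMBER_TO_SYMBOL[int(elements[0])].upper() in METAL_SYMBOLS:
                category = Category.METAL
            elif res_name in _NUCLEOTIDE_NAMES or is_nucleotide[lo]:
                category = Category.NUCLEOTIDE
            else:
                category = Category.SMALL_MOLECULE
            ctx_coords.append(array.coord[idx])
            ctx_elements.append(elements)
            ctx_category.append(np.full(len(idx), int(category)))
            ctx_mol.append(np.full(len(idx), mol_counter))
            mol_counter += 1

    if not bb_coords:
        raise StructureError(f"no protein residues in {path}")

    structure = ProteinStructure(
        backbone_coords=np.stack(bb_coords),
        residue_index=np.array(res_index),
        chain_labels=np.array(chain_labels),
        sequence=np.array(seq),
        residue_mask=np.array(res_mask),
        chain_ids=tuple(chain_order),
    )

    parts = []
    if ctx_coords:
        parts.append(ContextAtoms(
            np.concatenate(ctx_coords), np.concatenate(ctx_elements),
            np.concatenate(ctx_category),
            mol_id=np.concatenate(ctx_mol),
        ))
    if sc_coords:
        n_sc = sum(len(c) for c in sc_coords)
        parts.append(ContextAtoms(
            np.concatenate(sc_coords), np.concatenate(sc_elements),
            np.full(n_sc, int(Category.PROTEIN_SIDECHAIN)),
            residue_of=np.concatenate(sc_residue_of),
        ))
    context = ContextAtoms.concatenate(parts) if parts else ContextAtoms.empty()
    return structure, context


# ---------------------------------------------------------------------------
# writers


def write_fasta(designs, path) -> None:
    """One FASTA record per design, in input order."""
    fasta_file = _fasta.FastaFile()
    for i, design in enumerate(designs):
        header = (f"design_{i} id={i} T={design.temperature:g} "
                  f"confidence={design.confidence:.2f}")
        fasta_file[header] = decode_sequence(design.sequence)
    fasta_file.write(str(path))


def read_fasta(path) -> dict[str, str]:
    fasta_file = _fasta.FastaFile.read(str(path))
    return dict(fasta_file.items())


def write_design_json(designs, path) -> None:
    """JSON sidecar with per-position probabilities, orders and confidences."""
    payload = []
    for i, design in enumerate(designs):
        payload.append({
            "id": i,
            "sequence": decode_sequence(design.sequence),
            "temperature": design.temperature,
            "confidence": design.confidence,
            "decoding_order": design.decoding_order.tolist(),
            # floor -inf (impossible tokens) so the sidecar stays strict JSON
            "log_probs": np.maximum(design.log_probs, -1e9).tolist(),
        })
    Path(path).write_text(json.dumps(payload))


def _structure_to_atom_array(structure: ProteinStructure,
                             sidechain_coords: np.ndarray | None) -> struc.AtomArray:
    from .geometry import ATOM14_NAMES  # deferred: geometry imports no IO

    L = len(structure)
    if sidechain_coords is not None:
        sidechain_coords = np.asarray(sidechain_coords, dtype=np.float64)
        if sidechain_coords.shape != (L, 14, 3):
            raise ValueError(f"sidechain coordinate array must be [L,14,3], "
                             f"got {sidechain_coords.shape}")
    records = []
    for i in range(L):
        if not structure.residue_mask[i]:
            continue
        three = TOKEN_TO_THREE[int(structure.sequence[i])]
        names = ATOM14_NAMES.get(three, BACKBONE_ATOMS)
        chain = structure.chain_ids[structure.chain_labels[i]] \
            if structure.chain_ids else chr(ord("A") + int(structure.chain_labels[i]))
        for slot, name in enumerate(names):
            if slot < 4:
                xyz = structure.backbone_coords[i, slot]
            elif sidechain_coords is None:
                continue
            else:
                xyz = sidechain_coords[i, slot]
                if not np.isfinite(xyz).all():
                    continue
            records.append((chain, int(structure.residue_index[i]), three, name, xyz))
    array = struc.AtomArray(len(records))
    for j, (chain, res_id, res_name, name, xyz) in enumerate(records):
        array.chain_id[j] = chain
        array.res_id[j] = res_id
        array.res_name[j] = res_name
        array.atom_name[j] = name
        array.element[j] = name[0]
        array.coord[j] = xyz
        array.hetero[j] = False
    return array


def write_structure(structure: ProteinStructure,
                    sidechain_coords: np.ndarray | None,
                    path) -> None:
    """Write a PDB file with backbone plus (optionally) packed sidechains."""
    array = _structure_to_atom_array(structure, sidechain_coords)
    pdb_file = _pdb.PDBFile()
    _pdb.set_structure(pdb_file, array)
    pdb_file.write(str(path))


_CATEGORY_RES_NAME = {
    int(Category.SMALL_MOLECULE): "LIG",
    int(Category.NUCLEOTIDE): "DA",
    int(Category.METAL): None,  # metals use their element symbol
}


def write_structure_with_context(structure: ProteinStructure,
                                 context: ContextAtoms,
                                 path,
                                 sidechain_coords: np.ndarray | None = None) -> None:
    """Write protein ATOM records plus HETATM records for context atoms."""
    protein = _structure_to_atom_array(structure, sidechain_coords)
    ctx = context.without_sidechains()
    n = len(ctx)
    het = struc.AtomArray(n)
    next_res_id = int(structure.residue_index.max(initial=0)) + 10
    for j in range(n):
        symbol = NUMBER_TO_SYMBOL[int(ctx.element[j])]
        res_name = _CATEGORY_RES_NAME.get(int(ctx.category[j])) or symbol.upper()
        het.chain_id[j] = "X"
        het.res_id[j] = next_res_id + int(ctx.mol_id[j])
        het.res_name[j] = res_name
        het.atom_name[j] = f"{symbol.upper()}{j % 99 + 1}" \
            if int(ctx.category[j]) != int(Category.METAL) else symbol.upper()
        het.element[j] = symbol.upper()
        het.coord[j] = ctx.coords[j]
        het.hetero[j] = True
    combined = protein + het if n else protein
    pdb_file = _pdb.PDBFile()
    _pdb.set_structure(pdb_file, combined)
    pdb_file.write(str(path))
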
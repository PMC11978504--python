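"""Synthetic structures, context-atom clouds and planted-rule datasets.

Everything is generated from seeds, so every other module is testable without
any external files: idealized multi-chain backbones built from preset
secondary-structure dihedrals, atom clouds standing in for small molecules /
nucleotide fragments / metal ions, and datasets whose sequences follow a
planted proximity rule (residues close to a trigger element receive a forced
token) that a context-aware model can learn but a protein-only model cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import ONE_TO_TOKEN
from .geometry import build_backbone, virtual_cbeta
from .structures_io import Category, ContextAtoms, ProteinStructure
from .structures_io import write_structure_with_context

# textbook dihedral presets (degrees)
SS_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-119.0, 113.0),
}


@dataclass
class LigandSpec:
    """An atom cloud: single metals or connected molecule-like clouds."""

    n_atoms: int = 1
    elements: tuple[int, ...] = (30,)  # atomic numbers, cycled over atoms
    placement_radius: float = 3.0     # distance from the anchor residue's virtual CB
    anchor_residue: int | None = None  # None -> random residue
    category: int = int(Category.METAL)
    bond_length: float = 1.5


@dataclass
class PlantedRule:
    """Sequence rule: forced token near a trigger element, background elsewhere."""

    trigger_element: int = 30          # Zn
    trigger_radius: float = 3.5        # Angstrom, on virtual-CB distance
    forced_token: int = ONE_TO_TOKEN["H"]
    background_tokens: tuple[int, ...] = (
        ONE_TO_TOKEN["A"], ONE_TO_TOKEN["L"], ONE_TO_TOKEN["E"], ONE_TO_TOKEN["K"])
    background_probs: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.trigger_radius < 0:
            raise ValueError("trigger_radius must be >= 0")
        if self.background_probs is not None:
            p = np.asarray(self.background_probs, dtype=np.float64)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("background_probs must normalize")


@dataclass
class FixtureSpec:
    n_chains: int = 1
    chain_length: int = 20
    secondary_structure: str = "helix"
    dihedral_jitter_deg: float = 3.0
    chain_spacing: float = 18.0
    ligands: tuple[LigandSpec, ...] = ()
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_chains < 1 or self.chain_length < 1:
            raise ValueError("n_chains and chain_length must be >= 1")
        if self.secondary_structure not in SS_DIHEDRALS:
            raise ValueError(f"unknown secondary structure: {self.secondary_structure}")


def make_backbone(spec: FixtureSpec) -> ProteinStructure:
    """Idealized multi-chain backbone; consecutive CA-CA distances ~3.8 A."""
    rng = np.random.default_rng(spec.rng_seed)
    phi0, psi0 = SS_DIHEDRALS[spec.secondary_structure]
    L = spec.chain_length
    coords, res_index, chain_labels = [], [], []
    for c in range(spec.n_chains):
        jitter = np.deg2rad(spec.dihedral_jitter_deg)
        phi = np.deg2rad(phi0) + jitter * rng.standard_normal(L)
        psi = np.deg2rad(psi0) + jitter * rng.standard_normal(L)
        origin = np.array([0.0, 0.0, c * spec.chain_spacing])
        coords.append(build_backbone(phi, psi, origin=origin))
        res_index.extend(range(1, L + 1))
        chain_labels.extend([c] * L)
    total = spec.n_chains * L
    return ProteinStructure(
        backbone_coords=np.concatenate(coords),
        residue_index=np.array(res_index),
        chain_labels=np.array(chain_labels),
        sequence=np.zeros(total, dtype=np.int64),
        residue_mask=np.ones(total, dtype=bool),
        chain_ids=tuple(chr(ord("A") + c) for c in range(spec.n_chains)),
    )


def make_context(spec: FixtureSpec, backbone: ProteinStructure) -> ContextAtoms:
    """Place the spec's ligand clouds relative to the backbone.

    Single atoms land exactly at ``placement_radius`` from the anchor
    residue's virtual CB; multi-atom clouds grow as connected random walks
    with fixed bond lengths from that point.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    parts = []
    X = backbone.backbone_coords
    cb = virtual_cbeta(X[:, 0], X[:, 1], X[:, 2])
    for lig in spec.ligands:
        anchor = lig.anchor_residue
        if anchor is None:
            anchor = int(rng.integers(0, len(backbone)))
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        start = cb[anchor] + lig.placement_radius * direction
        coords = [start]
        for _ in range(lig.n_atoms - 1):
            step = rng.standard_normal(3)
            step /= np.linalg.norm(step)
            coords.append(coords[-1] + lig.bond_length * step)
        elements = [lig.elements[i % len(lig.elements)] for i in range(lig.n_atoms)]
        parts.append(ContextAtoms(
            np.asarray(coords), np.asarray(elements),
            np.full(lig.n_atoms, lig.category),
        ))
    return ContextAtoms.concatenate(parts) if parts else ContextAtoms.empty()


def apply_planted_rule(structure: ProteinStructure, context: ContextAtoms,
                       rule: PlantedRule,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Assign a sequence by the rule; returns (sequence, trigger_mask)."""
    L = len(structure)
    X = structure.backbone_coords
    cb = virtual_cbeta(X[:, 0], X[:, 1], X[:, 2])
    trigger = np.zeros(L, dtype=bool)
    hits = context.coords[context.element == rule.trigger_element]
    if len(hits) and rule.trigger_radius > 0:
        d = np.linalg.norm(cb[:, None, :] - hits[None, :, :], axis=-1)
        trigger = (d <= rule.trigger_radius).any(axis=1)
    probs = rule.background_probs
    seq = rng.choice(np.asarray(rule.background_tokens), size=L,
                     p=None if probs is None else np.asarray(probs))
    seq = seq.astype(np.int64)
    seq[trigger] = rule.forced_token
    return seq, trigger


@dataclass(eq=False)
class PlantedExample:
    structure: ProteinStructure
    context: ContextAtoms
    trigger_mask: np.ndarray


@dataclass
class PlantedDataset:
    train: list[PlantedExample] = field(default_factory=list)
    heldout: list[PlantedExample] = field(default_factory=list)
    rule: PlantedRule = field(default_factory=PlantedRule)


def make_planted_dataset(n_structures: int, rule: PlantedRule, seed: int,
                         chain_length: int = 60,
                         heldout_fraction: float = 0.2,
                         n_trigger_sites: int = 2,
                         trigger_placement_radius: float = 2.5,
                         n_decoys: int = 3,
                         decoy_radius: float = 12.0) -> PlantedDataset:
    """Seeded dataset of single-chain structures following the planted rule.

    Each structure carries trigger-element atoms near random residues (placed
    well inside the trigger radius so rule membership has a clean geometric
    margin) and a small carbon decoy cloud farther away; the held-out split
    is disjoint by structure.
    """
    rng = np.random.default_rng(seed)
    dataset = PlantedDataset(rule=rule)
    n_heldout = int(round(n_structures * heldout_fraction))
    margin = (rule.trigger_radius - 0.6, rule.trigger_radius + 0.7)
    for i in range(n_structures):
        ligands = [LigandSpec(n_atoms=1, elements=(rule.trigger_element,),
                              placement_radius=trigger_placement_radius,
                              category=int(Category.METAL))
                   for _ in range(n_trigger_sites)]
        if n_decoys > 0:
            ligands.append(LigandSpec(
                n_atoms=n_decoys, elements=(6,), placement_radius=decoy_radius,
                category=int(Category.SMALL_MOLECULE)))
        # re-roll placements that leave any residue inside the ambiguous band
        # around the trigger radius, so rule membership is geometrically crisp
        for _ in range(50):
            spec = FixtureSpec(chain_length=chain_length,
                               ligands=tuple(ligands),
                               rng_seed=int(rng.integers(0, 2**31)))
            structure = make_backbone(spec)
            context = make_context(spec, structure)
            X = structure.backbone_coords
            cb = virtual_cbeta(X[:, 0], X[:, 1], X[:, 2])
            hits = context.coords[context.element == rule.trigger_element]
            d = np.linalg.norm(cb[:, None, :] - hits[None, :, :], axis=-1)
            if not ((d > margin[0]) & (d < margin[1])).any():
                break
        seq, trigger = apply_planted_rule(structure, context, rule, rng)
        structure.sequence = seq
        example = PlantedExample(structure, context, trigger)
        if i < n_structures - n_heldout:
            dataset.train.append(example)
        else:
            dataset.heldout.append(example)
    return dataset


def write_fixture_pdb(structure: ProteinStructure, context: ContextAtoms,
                      path) -> None:
    """Serialize a fixture (protein ATOM + context HETATM records) as PDB."""
    write_structure_with_context(structure, context, path)
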
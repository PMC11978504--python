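"""Invariant geometric featurization of backbones and context atoms.

Everything here is plain numpy and deterministic: k-nearest-neighbor graph
construction on Cα positions, the 25 ordered backbone-atom-pair RBF blocks
(N/CA/C/O/virtual-CB against the same five atoms), relative-position indices
for the positional encoding, per-residue selection of the M closest context
atoms from the virtual CB, element one-hot decomposition, and local-frame
angle features. The learned projections of these blocks are part of the
network model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elements import MAX_ATOMIC_NUMBER, chemical_group, chemical_period
from .geometry import virtual_cbeta
from .structures_io import ContextAtoms, ProteinStructure

# element one-hot decomposition widths: atomic number + group + period
ELEMENT_ONEHOT_WIDTH = 120
GROUP_ONEHOT_WIDTH = 19
PERIOD_ONEHOT_WIDTH = 8
ELEMENT_FEATURE_WIDTH = ELEMENT_ONEHOT_WIDTH + GROUP_ONEHOT_WIDTH + PERIOD_ONEHOT_WIDTH

N_EDGE_ATOM_PAIRS = 25  # 5 x 5 ordered backbone atom pairs per edge
ANGLE_FEATURE_WIDTH = 4


@dataclass
class FeatureConfig:
    """Featurization metaparameters (defaults follow the reference settings)."""

    K: int = 32
    M: int = 25
    r: int = 16
    m: int = 128
    max_offset: int = 32
    noise_level: float = 0.1
    rbf_min: float = 2.0
    rbf_max: float = 22.0
    element_embed_dim: int = 64
    exclude_masked_neighbors: bool = False

    def __post_init__(self):
        if min(self.K, self.M, self.r, self.m) < 1:
            raise ValueError("K, M, r and m must all be >= 1")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    @property
    def pos_onehot_width(self) -> int:
        return 2 * self.max_offset + 2

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "FeatureConfig":
        import yaml
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    @property
    def edge_in_width(self) -> int:
        # positional embedding (16) + 25 RBF blocks
        return 16 + N_EDGE_ATOM_PAIRS * self.r

    @property
    def context_node_in_width(self) -> int:
        return 5 * self.r + self.element_embed_dim + ANGLE_FEATURE_WIDTH


@dataclass(eq=False)
class ResidueContext:
    """Per-residue M nearest context atoms: coords, mask and element numbers.

    Unmasked atoms are sorted by ascending distance to the residue's virtual
    CB; masked slots have zeroed coordinates and elements.
    """

    Y: np.ndarray     # [L, M, 3]
    Y_m: np.ndarray   # [L, M]
    Y_t: np.ndarray   # [L, M]


def backbone_atoms5(structure: ProteinStructure) -> np.ndarray:
    """[L, 5, 3] array of N, CA, C, O and virtual CB coordinates."""
    X = structure.backbone_coords
    cb = virtual_cbeta(X[:, 0], X[:, 1], X[:, 2])
    return np.concatenate([X, cb[:, None, :]], axis=1)


def rbf_encode(d: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Gaussian radial basis activations of distances, appended as a last axis.

    Centers are evenly spaced on [rbf_min, rbf_max]; the width equals the
    center spacing.
    """
    d = np.asarray(d, dtype=np.float64)
    centers = np.linspace(config.rbf_min, config.rbf_max, config.r)
    sigma = centers[1] - centers[0] if config.r > 1 else (config.rbf_max - config.rbf_min)
    z = (d[..., None] - centers) / sigma
    return np.exp(-z * z)


def topk_neighbors(structure: ProteinStructure, config: FeatureConfig) -> np.ndarray:
    """[L, min(K, L)] indices of the nearest residues by CA-CA distance.

    Every residue is its own nearest neighbor (distance zero); ties are broken
    by lower residue index via a stable sort.
    """
    ca = structure.backbone_coords[:, 1]
    L = ca.shape[0]
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    if config.exclude_masked_neighbors:
        bad = ~structure.residue_mask
        d = d + 1e6 * bad[None, :]
    k = min(config.K, L)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k].astype(np.int64)


def neighbor_offsets(structure: ProteinStructure,
                     e_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residue-index offsets and same-chain mask gathered on the edge list."""
    r_idx = structure.residue_index
    chains = structure.chain_labels
    offset = r_idx[:, None] - r_idx[e_idx]
    same_chain = (chains[:, None] == chains[e_idx]).astype(np.int64)
    return offset, same_chain


def positional_index(offset: np.ndarray, same_chain: np.ndarray,
                     config: FeatureConfig) -> np.ndarray:
    """Integer bin of each edge for the positional one-hot.

    Same-chain edges use ``clip(offset + max_offset, 0, 2*max_offset)``;
    cross-chain edges all map to the extra bin ``2*max_offset + 1``.
    """
    d = same_chain * np.clip(offset + config.max_offset, 0, 2 * config.max_offset)
    f = (1 - same_chain) * (2 * config.max_offset + 1)
    return (d + f).astype(np.int64)


def positional_onehot(offset: np.ndarray, same_chain: np.ndarray,
                      config: FeatureConfig) -> np.ndarray:
    g = positional_index(offset, same_chain, config)
    return np.eye(config.pos_onehot_width)[g]


def edge_rbf_blocks(structure: ProteinStructure, e_idx: np.ndarray,
                    config: FeatureConfig) -> np.ndarray:
    """[L, K, 25*r]: RBF of ||a_i - b_j|| for all ordered pairs of the five
    backbone atoms (N, CA, C, O, virtual CB), in nested loop order."""
    atoms = backbone_atoms5(structure)
    blocks = []
    for a in range(5):
        ai = atoms[:, a][:, None, :]          # [L, 1, 3]
        for b in range(5):
            bj = atoms[e_idx, b]              # [L, K, 3]
            dist = np.linalg.norm(ai - bj, axis=-1)
            blocks.append(rbf_encode(dist, config))
    return np.concatenate(blocks, axis=-1)


def build_protein_graph(structure: ProteinStructure,
                        config: FeatureConfig) -> dict[str, np.ndarray]:
    """Numeric protein-graph features prior to the learned projection."""
    e_idx = topk_neighbors(structure, config)
    rbf = edge_rbf_blocks(structure, e_idx, config)
    offset, same_chain = neighbor_offsets(structure, e_idx)
    return {
        "e_idx": e_idx,
        "rbf": rbf,
        "pos_onehot": positional_onehot(offset, same_chain, config),
    }


def select_context_atoms(structure: ProteinStructure, context: ContextAtoms,
                         config: FeatureConfig,
                         include_sidechains: bool = False,
                         sidechain_residues: np.ndarray | None = None,
                         exclude_own: bool = True) -> ResidueContext:
    """Per residue, the M nearest context atoms by virtual-CB distance.

    Sidechain-category atoms are excluded unless ``include_sidechains`` is
    set, in which case ``sidechain_residues`` (a boolean [L] selector) limits
    which residues donate their atoms. With ``exclude_own`` (the default,
    used for sequence design) a residue never receives its own sidechain
    atoms as context; sidechain packing disables this so a residue's already
    placed atoms can condition its later chi angles.
    """
    L = len(structure)
    M = config.M
    Y = np.zeros((L, M, 3))
    Y_m = np.zeros((L, M))
    Y_t = np.zeros((L, M), dtype=np.int64)
    if len(context) == 0:
        return ResidueContext(Y, Y_m, Y_t)

    is_sc = context.category == 3  # Category.PROTEIN_SIDECHAIN
    if include_sidechains:
        keep = ~is_sc
        if sidechain_residues is not None:
            donate = np.zeros(L, dtype=bool)
            donate[np.asarray(sidechain_residues)] = True
            keep = keep | (is_sc & donate[np.clip(context.residue_of, 0, None)])
        else:
            keep = np.ones(len(context), dtype=bool)
    else:
        keep = ~is_sc
    atoms = context.subset(keep)
    if len(atoms) == 0:
        return ResidueContext(Y, Y_m, Y_t)

    X = structure.backbone_coords
    cb = virtual_cbeta(X[:, 0], X[:, 1], X[:, 2])
    d = np.linalg.norm(cb[:, None, :] - atoms.coords[None, :, :], axis=-1)
    if exclude_own:
        own = atoms.residue_of[None, :] == np.arange(L)[:, None]
        d = np.where(own, np.inf, d)
    order = np.argsort(d, axis=1, kind="stable")
    n_take = min(M, len(atoms))
    for i in range(L):
        sel = order[i, :n_take]
        sel = sel[np.isfinite(d[i, sel])]
        Y[i, :len(sel)] = atoms.coords[sel]
        Y_t[i, :len(sel)] = atoms.element[sel]
        Y_m[i, :len(sel)] = 1.0
    return ResidueContext(Y, Y_m, Y_t)


_GROUP_TABLE = np.array([0] + [chemical_group(z) for z in range(1, MAX_ATOMIC_NUMBER + 1)])
_PERIOD_TABLE = np.array([0] + [chemical_period(z) for z in range(1, MAX_ATOMIC_NUMBER + 1)])


def element_onehot(Y_t: np.ndarray) -> np.ndarray:
    """[..., 147] one-hot decomposition: atomic number, group, period."""
    Y_t = np.asarray(Y_t, dtype=np.int64)
    z = np.clip(Y_t, 0, ELEMENT_ONEHOT_WIDTH - 1)
    group = _GROUP_TABLE[np.clip(Y_t, 0, MAX_ATOMIC_NUMBER)]
    period = _PERIOD_TABLE[np.clip(Y_t, 0, MAX_ATOMIC_NUMBER)]
    out = np.zeros(Y_t.shape + (ELEMENT_FEATURE_WIDTH,))
    idx = np.indices(Y_t.shape)
    out[(*idx, z)] = 1.0
    out[(*idx, ELEMENT_ONEHOT_WIDTH + group)] = 1.0
    out[(*idx, ELEMENT_ONEHOT_WIDTH + GROUP_ONEHOT_WIDTH + period)] = 1.0
    return out


def local_frame_angles(structure: ProteinStructure, Y: np.ndarray) -> np.ndarray:
    """[L, M, 4] sin/cos of azimuth and polar angles of each context atom in
    the residue's orthonormal N-CA-C frame (origin CA)."""
    X = structure.backbone_coords
    n, ca, c = X[:, 0], X[:, 1], X[:, 2]

    def _norm(v):
        length = np.linalg.norm(v, axis=-1, keepdims=True)
        return v / np.where(length < 1e-8, 1.0, length)

    x_axis = _norm(n - ca)
    z_axis = _norm(np.cross(x_axis, c - ca))
    y_axis = np.cross(z_axis, x_axis)
    rel = Y - ca[:, None, :]
    u = _norm(rel)
    ux = np.einsum("lmk,lk->lm", u, x_axis)
    uy = np.einsum("lmk,lk->lm", u, y_axis)
    uz = np.einsum("lmk,lk->lm", u, z_axis)
    azimuth = np.arctan2(uy, ux)
    polar = np.arccos(np.clip(uz, -1.0, 1.0))
    return np.stack([np.sin(azimuth), np.cos(azimuth),
                     np.sin(polar), np.cos(polar)], axis=-1)


def context_feature_blocks(structure: ProteinStructure, rc: ResidueContext,
                           config: FeatureConfig) -> dict[str, np.ndarray]:
    """Numeric context blocks prior to the learned projections.

    Masked slots are zeroed so arbitrary placeholder coordinates cannot leak
    downstream.
    """
    atoms = backbone_atoms5(structure)
    m = rc.Y_m[..., None]
    blocks = []
    for a in range(5):
        dist = np.linalg.norm(atoms[:, a][:, None, :] - rc.Y, axis=-1)
        blocks.append(rbf_encode(dist, config) * m)
    rbf_y = np.concatenate(blocks, axis=-1)
    onehot = element_onehot(rc.Y_t) * m
    angles = local_frame_angles(structure, rc.Y) * m
    dyy = np.linalg.norm(rc.Y[:, :, None, :] - rc.Y[:, None, :, :], axis=-1)
    pair_mask = (rc.Y_m[:, :, None] * rc.Y_m[:, None, :])[..., None]
    y_edges_rbf = rbf_encode(dyy, config) * pair_mask
    return {
        "rbf_y": rbf_y,
        "element_onehot": onehot,
        "angles": angles,
        "y_edges_rbf": y_edges_rbf,
    }


def add_coordinate_noise(structure: ProteinStructure, context: ContextAtoms,
                         noise_level: float,
                         rng: np.random.Generator | int) -> tuple[ProteinStructure, ContextAtoms]:
    """I.i.d. Gaussian perturbation of all coordinates; level 0 is identity."""
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    noised = structure.copy()
    ctx = ContextAtoms(context.coords.copy(), context.element.copy(),
                       context.category.copy(), context.residue_of.copy(),
                       context.mol_id.copy())
    if noise_level > 0:
        noised.backbone_coords = noised.backbone_coords + \
            noise_level * rng.standard_normal(noised.backbone_coords.shape)
        if len(ctx):
            ctx.coords = ctx.coords + noise_level * rng.standard_normal(ctx.coords.shape)
    return noised, ctx
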
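"""Sidechain packing: circular-normal (von Mises) mixture prediction over the
four chi angles and stage-wise decoding into full-atom coordinates.

Decoding runs in four stages — all chi1 angles, then chi2, chi3, chi4. After
each stage the newly placed atoms are fed back as additional context atoms
(category ``PROTEIN_SIDECHAIN``), so later chi angles are conditioned on the
already-built geometry of the residue itself and of its neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import TOKEN_TO_THREE
from .elements import SYMBOL_TO_NUMBER
from .featurization import ResidueContext, select_context_atoms
from .geometry import (ATOM14_NAMES, CHI_COUNT, chi_level_of_atoms,
                       measure_chis, place_sidechain, wrap_angle)
from .nn import tensor as T
from .nn.model import SidechainPackerModel
from .structures_io import Category, ContextAtoms, ProteinStructure

TWO_PI = 2.0 * np.pi


@dataclass(eq=False)
class TorsionMixture:
    """Per-residue, per-chi mixture parameters (three components each)."""

    mean: np.ndarray           # [L, 4, 3] radians, wrapped to (-pi, pi]
    concentration: np.ndarray  # [L, 4, 3], > 0.1
    mix_logits: np.ndarray     # [L, 4, 3]

    @property
    def weights(self) -> np.ndarray:
        z = self.mix_logits - self.mix_logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)


@dataclass(eq=False)
class ChiSet:
    chi: np.ndarray        # [L, 4] radians; NaN where invalid
    chi_mask: np.ndarray   # [L, 4] True where the residue has that chi
    coords: np.ndarray     # [L, 14, 3]; NaN for absent atoms
    log_probs: np.ndarray  # [L, 4] log density at the decoded chi; NaN invalid


def chi_mask_for_sequence(sequence: np.ndarray) -> np.ndarray:
    """[L, 4] validity mask from per-residue chi counts."""
    counts = np.array([CHI_COUNT.get(TOKEN_TO_THREE[int(t)], 0)
                       for t in np.asarray(sequence)])
    return np.arange(4)[None, :] < counts[:, None]


def mixture_log_density(mixture: TorsionMixture, chi: np.ndarray) -> np.ndarray:
    """Log density of the von Mises mixture at ``chi`` ([L, 4] or broadcastable).

    Invariant to 2*pi shifts of the observations.
    """
    from scipy.special import i0e

    x = np.asarray(chi, dtype=np.float64)[..., None]
    kappa = mixture.concentration
    comp = kappa * np.cos(x - mixture.mean) - np.log(TWO_PI) \
        - (np.log(i0e(kappa)) + kappa)
    logw = mixture.mix_logits - mixture.mix_logits.max(axis=-1, keepdims=True)
    logw = logw - np.log(np.exp(logw).sum(axis=-1, keepdims=True))
    z = logw + comp
    zmax = z.max(axis=-1)
    return zmax + np.log(np.exp(z - zmax[..., None]).sum(axis=-1))


def torsion_nll(mixture: TorsionMixture, chi: np.ndarray,
                chi_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-chi negative log-likelihood; masked entries are NaN."""
    nll = -mixture_log_density(mixture, chi)
    if chi_mask is not None:
        nll = np.where(np.asarray(chi_mask, dtype=bool), nll, np.nan)
    return nll


def torsion_nll_loss(mean, concentration, mix_logits, chi: np.ndarray,
                     chi_mask: np.ndarray):
    """Differentiable masked-mean NLL on network outputs (Tensor inputs)."""
    x = np.asarray(chi, dtype=np.float64)
    mask = np.asarray(chi_mask, dtype=np.float64)
    xs = np.where(np.isfinite(x), x, 0.0)[..., None]
    comp = concentration * T.cos(T.as_tensor(xs) - mean) \
        - np.log(TWO_PI) - T.log_bessel_i0(concentration)
    logw = T.log_softmax(mix_logits, axis=-1)
    log_density = T.logsumexp(logw + comp, axis=-1)
    total = T.tsum(log_density * mask)
    denom = max(mask.sum(), 1.0)
    return -total * (1.0 / denom)


def sample_mixture(mixture: TorsionMixture, rng: np.random.Generator) -> np.ndarray:
    """Draw one chi per residue/chi slot from the mixture."""
    shape = mixture.mean.shape[:-1]
    w = mixture.weights.reshape(-1, 3)
    cum = np.cumsum(w, axis=-1)
    u = rng.random(w.shape[0])[:, None]
    comp = (u > cum).sum(axis=-1).reshape(shape)
    comp = np.clip(comp, 0, 2)
    idx = np.indices(shape)
    mu = mixture.mean[(*idx, comp)]
    kappa = mixture.concentration[(*idx, comp)]
    return wrap_angle(mu + rng.vonmises(0.0, kappa))


def mode_mixture(mixture: TorsionMixture) -> np.ndarray:
    """Mean of the highest-weight component per chi."""
    comp = mixture.mix_logits.argmax(axis=-1)
    idx = np.indices(comp.shape)
    return mixture.mean[idx[0], idx[1], comp]


_SIDECHAIN_SLOTS = slice(4, 14)


def _placed_atoms_as_context(sequence: np.ndarray, coords: np.ndarray,
                             upto_level: int) -> ContextAtoms:
    """Sidechain atoms placed so far (chi level <= upto_level), as context."""
    xyz, elements, residue_of = [], [], []
    for i, tok in enumerate(np.asarray(sequence)):
        three = TOKEN_TO_THREE[int(tok)]
        names = ATOM14_NAMES.get(three, ATOM14_NAMES["UNK"])
        levels = chi_level_of_atoms(three)
        for slot in range(4, len(names)):
            name = names[slot]
            if levels.get(name, 0) > upto_level:
                continue
            if not np.isfinite(coords[i, slot]).all():
                continue
            xyz.append(coords[i, slot])
            elements.append(SYMBOL_TO_NUMBER[name[0]])
            residue_of.append(i)
    if not xyz:
        return ContextAtoms.empty()
    n = len(xyz)
    return ContextAtoms(np.asarray(xyz), np.asarray(elements),
                        np.full(n, int(Category.PROTEIN_SIDECHAIN)),
                        residue_of=np.asarray(residue_of))


def predict_torsion_distribution(packer: SidechainPackerModel,
                                 structure: ProteinStructure,
                                 sequence: np.ndarray,
                                 rc: ResidueContext | None,
                                 decoding_order: np.ndarray | None = None) -> TorsionMixture:
    """Run the packing network once; returns the full mixture."""
    L = len(structure)
    if decoding_order is None:
        decoding_order = np.arange(L)
    with T.no_grad():
        mean, conc, logits = packer(structure, sequence, rc, decoding_order)
    return TorsionMixture(mean.data.copy(), conc.data.copy(), logits.data.copy())


def decode_sidechains(packer: SidechainPackerModel,
                      structure: ProteinStructure,
                      sequence: np.ndarray,
                      context: ContextAtoms | None = None,
                      mode: str = "mode",
                      rng_seed: int = 0) -> ChiSet:
    """Four-stage chi decoding with coordinate feedback between stages."""
    if mode not in ("sample", "mode"):
        raise ValueError(f"unknown mode: {mode}")
    sequence = np.asarray(sequence, dtype=np.int64)
    L = len(structure)
    rng = np.random.default_rng(rng_seed)
    base_ctx = (context or ContextAtoms.empty()).without_sidechains()
    chi = np.full((L, 4), np.nan)
    log_probs = np.full((L, 4), np.nan)
    mask = chi_mask_for_sequence(sequence)
    coords = np.stack([
        place_sidechain(TOKEN_TO_THREE[int(sequence[i])],
                        structure.backbone_coords[i], np.zeros(4), max_chi=0)
        for i in range(L)])
    order = rng.permutation(L)
    for stage in range(1, 5):
        if not mask[:, stage - 1].any():
            continue
        placed = _placed_atoms_as_context(sequence, coords, stage - 1)
        ctx_stage = ContextAtoms.concatenate([base_ctx, placed])
        rc = select_context_atoms(structure, ctx_stage, packer.feature_config,
                                  include_sidechains=True, exclude_own=False)
        mixture = predict_torsion_distribution(packer, structure, sequence,
                                               rc, decoding_order=order)
        draws = sample_mixture(mixture, rng) if mode == "sample" \
            else mode_mixture(mixture)
        active = mask[:, stage - 1]
        chi[active, stage - 1] = draws[active, stage - 1]
        dens = mixture_log_density(mixture, np.where(np.isfinite(chi), chi, 0.0))
        log_probs[active, stage - 1] = dens[active, stage - 1]
        for i in np.where(active)[0]:
            coords[i] = place_sidechain(
                TOKEN_TO_THREE[int(sequence[i])], structure.backbone_coords[i],
                np.where(np.isfinite(chi[i]), chi[i], 0.0), max_chi=stage)
    return ChiSet(chi=chi, chi_mask=mask, coords=coords, log_probs=log_probs)


def chis_to_coords(res_name: str, backbone: np.ndarray,
                   chi: np.ndarray) -> np.ndarray:
    """Full-atom coordinates for one residue from its chi angles (atom14)."""
    return place_sidechain(res_name, backbone, chi)


def measure_native_chis(structure: ProteinStructure,
                        atom14: np.ndarray) -> ChiSet:
    """Measure chi angles from given full-atom coordinates."""
    L = len(structure)
    chi = np.stack([measure_chis(TOKEN_TO_THREE[int(structure.sequence[i])],
                                 atom14[i]) for i in range(L)])
    mask = chi_mask_for_sequence(structure.sequence) & np.isfinite(chi)
    return ChiSet(chi=chi, chi_mask=mask, coords=np.asarray(atom14),
                  log_probs=np.full((L, 4), np.nan))
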
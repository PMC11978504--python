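"""Losses, augmentations, token-budget batching and the desk-scale training
loop, plus held-out recovery evaluation.

Batching packs several structures into one disconnected super-structure:
each member is translated far from the others so the k-nearest-neighbor graph
and context selection never cross structure boundaries, while chain labels
stay distinct so positional encodings treat members as separate chains.
Per-residue context is selected per member (before packing) and concatenated
row-wise, which makes the packed forward pass equivalent to the unpacked one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .design import DesignRequest, sample_sequence
from .featurization import ResidueContext, add_coordinate_noise, select_context_atoms
from .nn import tensor as T
from .nn.layers import Adam, load_checkpoint, save_checkpoint
from .nn.model import SequenceDesignModel
from .structures_io import ContextAtoms, ProteinStructure

PACK_SPACING = 1000.0  # Angstrom between packed structures


@dataclass
class TrainConfig:
    lr: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.98
    adam_eps: float = 1e-9
    batch_tokens: int = 6000
    epochs: int = 10
    noise_level: float = 0.1
    sidechain_context_fraction: tuple[float, float] = (0.02, 0.04)
    rng_seed: int = 0
    warmup_steps: int = 0
    resolution_cutoff: float = 3.5
    max_length: int = 6000

    def __post_init__(self):
        self.sidechain_context_fraction = tuple(self.sidechain_context_fraction)
        lo, hi = self.sidechain_context_fraction
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("sidechain_context_fraction must be within [0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict
        payload = asdict(self)
        payload["sidechain_context_fraction"] = list(
            payload["sidechain_context_fraction"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass(eq=False)
class TrainExample:
    structure: ProteinStructure
    context: ContextAtoms
    cluster: int = 0
    resolution: float | None = None


def sequence_loss(log_probs, S: np.ndarray, residue_mask: np.ndarray):
    """Masked mean negative log-probability of the true tokens."""
    S = np.asarray(S, dtype=np.int64)
    mask = np.asarray(residue_mask, dtype=np.float64)
    L = S.shape[0]
    gathered = log_probs[np.arange(L), S]
    denom = max(mask.sum(), 1.0)
    return -T.tsum(gathered * mask) * (1.0 / denom)


def filter_dataset(examples: list[TrainExample], config: TrainConfig,
                   warn=print) -> list[TrainExample]:
    """Resolution/length filters applied from metadata when available."""
    kept = []
    for ex in examples:
        if len(ex.structure) >= config.max_length:
            continue
        if ex.resolution is None:
            pass  # no metadata: keep (warned once below)
        elif ex.resolution > config.resolution_cutoff:
            continue
        kept.append(ex)
    if any(ex.resolution is None for ex in kept):
        warn("warning: resolution metadata missing for some structures; "
             "resolution filter skipped for those")
    return kept


def load_cluster_table(path) -> dict[str, int]:
    """Two-column TSV (structure id -> cluster id)."""
    table = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, value = line.split("\t")[:2]
        table[key] = int(value)
    return table


def split_by_cluster(ids: list[str], table: dict[str, int],
                     heldout_fraction: float, seed: int) -> tuple[list[str], list[str]]:
    """Train/held-out split keeping whole clusters together."""
    clusters = sorted({table[i] for i in ids})
    rng = np.random.default_rng(seed)
    rng.shuffle(clusters)
    n_heldout = int(round(len(clusters) * heldout_fraction))
    heldout_clusters = set(clusters[:n_heldout])
    train = [i for i in ids if table[i] not in heldout_clusters]
    heldout = [i for i in ids if table[i] in heldout_clusters]
    return train, heldout


def augment_sidechain_context(examples: list[TrainExample],
                              fraction_range: tuple[float, float],
                              rng: np.random.Generator) -> list[np.ndarray]:
    """Per example, a boolean [L] array of residues donating sidechain atoms.

    One donation fraction is drawn uniformly from ``fraction_range`` per
    batch; residues are then selected independently with that probability.
    """
    lo, hi = fraction_range
    fraction = rng.uniform(lo, hi)
    return [rng.random(len(ex.structure)) < fraction for ex in examples]


def pack_structures(examples: list[tuple[ProteinStructure, ResidueContext]]
                    ) -> tuple[ProteinStructure, ResidueContext]:
    """Concatenate structures into one spatially separated super-structure."""
    coords, res_idx, chains, seq, mask = [], [], [], [], []
    Y, Y_m, Y_t = [], [], []
    chain_offset = 0
    for i, (s, rc) in enumerate(examples):
        shift = np.array([i * PACK_SPACING, 0.0, 0.0])
        coords.append(s.backbone_coords + shift)
        res_idx.append(s.residue_index)
        chains.append(s.chain_labels + chain_offset)
        chain_offset += int(s.chain_labels.max(initial=0)) + 1
        seq.append(s.sequence)
        mask.append(s.residue_mask)
        Y.append(rc.Y + shift * rc.Y_m[..., None])
        Y_m.append(rc.Y_m)
        Y_t.append(rc.Y_t)
    packed = ProteinStructure(np.concatenate(coords), np.concatenate(res_idx),
                              np.concatenate(chains), np.concatenate(seq),
                              np.concatenate(mask))
    rc = ResidueContext(np.concatenate(Y), np.concatenate(Y_m), np.concatenate(Y_t))
    return packed, rc


def _token_batches(examples: list[TrainExample], batch_tokens: int,
                   rng: np.random.Generator) -> list[list[TrainExample]]:
    order = rng.permutation(len(examples))
    batches, current, tokens = [], [], 0
    for idx in order:
        ex = examples[int(idx)]
        if current and tokens + len(ex.structure) > batch_tokens:
            batches.append(current)
            current, tokens = [], 0
        current.append(ex)
        tokens += len(ex.structure)
    if current:
        batches.append(current)
    return batches


@dataclass
class TrainResult:
    loss_curve: list[float] = field(default_factory=list)
    steps: int = 0


def train(model: SequenceDesignModel, examples: list[TrainExample],
          config: TrainConfig, checkpoint_path=None,
          resume: bool = False) -> TrainResult:
    """Desk-scale training loop: seeded, resumable, token-budget batched."""
    if not examples:
        raise ValueError("empty dataset")
    optimizer = Adam(model.parameters(), lr=config.lr,
                     betas=(config.adam_beta1, config.adam_beta2),
                     eps=config.adam_eps)
    result = TrainResult()
    start_epoch = 0
    if resume and checkpoint_path is not None and Path(checkpoint_path).exists():
        manifest = load_checkpoint(checkpoint_path, model, optimizer)
        start_epoch = int(manifest.get("extra", {}).get("epoch", 0))
        result.steps = optimizer.step_count
    model.train()
    fc = model.feature_config
    for epoch in range(start_epoch, config.epochs):
        # per-epoch stream keyed to the seed and epoch so runs are
        # reproducible and resumable mid-training
        rng = np.random.default_rng((config.rng_seed, epoch))
        for batch in _token_batches(examples, config.batch_tokens, rng):
            donors = augment_sidechain_context(
                batch, config.sidechain_context_fraction, rng)
            members = []
            for ex, donate in zip(batch, donors):
                noised_s, noised_ctx = add_coordinate_noise(
                    ex.structure, ex.context, config.noise_level, rng)
                rc = select_context_atoms(
                    noised_s, noised_ctx, fc,
                    include_sidechains=bool(donate.any()),
                    sidechain_residues=np.where(donate)[0])
                members.append((noised_s, rc))
            packed, rc = pack_structures(members)
            order = rng.permutation(len(packed))
            state = model.encode(packed, rc)
            _, log_probs = model.decode_logits(state, packed.sequence, order)
            loss = sequence_loss(log_probs, packed.sequence, packed.residue_mask)
            model.zero_grad()
            loss.backward()
            if config.warmup_steps > 0 and optimizer.step_count < config.warmup_steps:
                optimizer.lr = config.lr * (optimizer.step_count + 1) / config.warmup_steps
            else:
                optimizer.lr = config.lr
            optimizer.step()
            result.loss_curve.append(float(loss.data))
            result.steps += 1
        if checkpoint_path is not None:
            save_checkpoint(checkpoint_path, model, model.config_dict(),
                            optimizer, extra={"epoch": epoch + 1})
    model.eval()
    return result


def evaluate_recovery(model: SequenceDesignModel, examples: list[TrainExample],
                      position_sets: list[np.ndarray], n_designs: int = 1,
                      temperature: float = 1e-4, rng_seed: int = 0
                      ) -> tuple[list[float], list[float]]:
    """Sampled-sequence recovery at the given positions, per structure.

    Returns (per-structure recovery fractions, per-structure confidences).
    """
    model.eval()
    recoveries, confidences = [], []
    rng = np.random.default_rng(rng_seed)
    for ex, positions in zip(examples, position_sets):
        rc = select_context_atoms(ex.structure, ex.context, model.feature_config)
        with T.no_grad():
            state = model.encode(ex.structure, rc)
        request = DesignRequest(temperature=temperature, n_designs=n_designs)
        hits, confs = [], []
        for _ in range(n_designs):
            design = sample_sequence(model, state, request, rng)
            confs.append(design.confidence)
            if len(positions):
                hits.append(np.mean(
                    design.sequence[positions] == ex.structure.sequence[positions]))
        recoveries.append(float(np.mean(hits)) if hits else float("nan"))
        confidences.append(float(np.mean(confs)))
    return recoveries, confidences
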
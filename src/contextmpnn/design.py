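"""Autoregressive sequence design: sampling, constraints, tied positions,
and teacher-forced scoring.

Sampling visits positions in a uniformly random (seeded) decoding order. At
each step the decoder is re-run teacher-forced on the partially filled
sequence — the causal mask guarantees that not-yet-decoded tokens are never
attended, so this is exactly equivalent to incremental decoding. Tied groups
are decoded together when their earliest member's turn arrives, from the
average of the members' probability vectors; fixed positions emit their token
with probability one. The unknown token is excluded from sampling by default
(a -inf bias) while remaining part of the alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import ALPHABET_SIZE, UNKNOWN_TOKEN
from .featurization import ResidueContext, select_context_atoms
from .nn import tensor as T
from .nn.model import EncodedState, SequenceDesignModel
from .structures_io import ContextAtoms, ProteinStructure

NEG_INF = -1e9


@dataclass
class DesignRequest:
    temperature: float = 0.1
    bias: np.ndarray | None = None                 # [L, 21]
    fixed_positions: dict[int, int] = field(default_factory=dict)
    tied_groups: tuple[tuple[int, ...], ...] = ()
    n_designs: int = 1
    rng_seed: int = 0
    allow_unknown: bool = False

    def validate(self, L: int) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        for pos, tok in self.fixed_positions.items():
            if not 0 <= pos < L:
                raise ValueError(f"fixed position {pos} out of range")
            if not 0 <= tok < ALPHABET_SIZE:
                raise ValueError(f"fixed token {tok} out of range")
        seen: set[int] = set()
        for group in self.tied_groups:
            for pos in group:
                if not 0 <= pos < L:
                    raise ValueError(f"tied position {pos} out of range")
                if pos in seen:
                    raise ValueError("tied groups must be disjoint")
                if pos in self.fixed_positions:
                    raise ValueError("tied positions cannot also be fixed")
                seen.add(pos)


@dataclass(eq=False)
class DesignResult:
    sequence: np.ndarray        # [L]
    log_probs: np.ndarray       # [L, 21] log of the per-step sampling distribution
    decoding_order: np.ndarray  # [L]
    confidence: float           # 100 x mean emitted-token probability
    temperature: float


def _effective_bias(request: DesignRequest, L: int) -> np.ndarray:
    bias = np.zeros((L, ALPHABET_SIZE))
    if request.bias is not None:
        bias = bias + np.asarray(request.bias, dtype=np.float64)
    if not request.allow_unknown:
        bias[:, UNKNOWN_TOKEN] += NEG_INF
    return bias


def _stable_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sample_sequence(model: SequenceDesignModel, state: EncodedState,
                    request: DesignRequest,
                    rng: np.random.Generator | None = None) -> DesignResult:
    """Draw one design from the encoded structure."""
    L = state.e_idx.shape[0]
    request.validate(L)
    rng = np.random.default_rng(request.rng_seed) if rng is None else rng
    order = rng.permutation(L)
    bias = _effective_bias(request, L)

    group_of: dict[int, tuple[int, ...]] = {}
    for group in request.tied_groups:
        for pos in group:
            group_of[pos] = tuple(group)

    S = np.full(L, UNKNOWN_TOKEN, dtype=np.int64)
    probs = np.zeros((L, ALPHABET_SIZE))
    decoded = np.zeros(L, dtype=bool)
    designable = np.ones(L, dtype=bool)
    for pos, tok in request.fixed_positions.items():
        designable[pos] = False

    with T.no_grad():
        for i in order:
            if decoded[i]:
                continue
            if i in request.fixed_positions:
                tok = request.fixed_positions[i]
                S[i] = tok
                probs[i] = 0.0
                probs[i, tok] = 1.0
                decoded[i] = True
                continue
            logits, _ = model.decode_logits(state, S, order)
            members = [j for j in group_of.get(i, (i,)) if not decoded[j]]
            p = np.mean([_stable_softmax((logits.data[j] + bias[j]) / request.temperature)
                         for j in members], axis=0)
            p = p / p.sum()
            tok = int(rng.choice(ALPHABET_SIZE, p=p))
            for j in members:
                S[j] = tok
                probs[j] = p
                decoded[j] = True

    valid = designable & state.mask.astype(bool)
    emitted = probs[np.arange(L), S]
    confidence = float(100.0 * emitted[valid].mean()) if valid.any() else 0.0
    with np.errstate(divide="ignore"):
        log_probs = np.log(probs)
    return DesignResult(sequence=S, log_probs=log_probs, decoding_order=order,
                        confidence=confidence, temperature=request.temperature)


def design_sequences(model: SequenceDesignModel, structure: ProteinStructure,
                     context: ContextAtoms | None = None,
                     request: DesignRequest | None = None,
                     rc: ResidueContext | None = None) -> list[DesignResult]:
    """Encode once, then draw ``n_designs`` samples."""
    request = request or DesignRequest()
    if rc is None and context is not None:
        rc = select_context_atoms(structure, context, model.feature_config)
    rng = np.random.default_rng(request.rng_seed)
    with T.no_grad():
        state = model.encode(structure, rc)
        return [sample_sequence(model, state, request, rng)
                for _ in range(request.n_designs)]


def score_sequence(model: SequenceDesignModel, state: EncodedState,
                   S: np.ndarray, n_orders: int = 1,
                   rng_seed: int = 0) -> np.ndarray:
    """Per-position log-probability of ``S`` averaged over random decoding
    orders (teacher-forced, unit temperature, no bias)."""
    S = np.asarray(S, dtype=np.int64)
    L = state.e_idx.shape[0]
    rng = np.random.default_rng(rng_seed)
    total = np.zeros(L)
    with T.no_grad():
        for _ in range(n_orders):
            order = rng.permutation(L)
            _, log_probs = model.decode_logits(state, S, order)
            total += log_probs.data[np.arange(L), S]
    return total / n_orders
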
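"""Evaluation metrics: context-shell membership, sequence recovery, chi-angle
recovery with circular wraparound and symmetric-terminus handling, and
confidence calibration. All operations are pure functions of their inputs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import TOKEN_TO_THREE
from .geometry import SYMMETRIC_CHI, virtual_cbeta, wrap_angle
from .structures_io import ContextAtoms, ProteinStructure


def context_shell_residues(structure: ProteinStructure, context: ContextAtoms,
                           radius: float = 5.0,
                           sidechain_coords: np.ndarray | None = None) -> np.ndarray:
    """Positions with any sidechain atom within ``radius`` of a context atom.

    Native sidechain coordinates ([L, 14, 3], NaN-padded) define the shell
    when available; otherwise the virtual CB substitutes.
    """
    ctx = context.without_sidechains()
    L = len(structure)
    if len(ctx) == 0:
        return np.zeros(0, dtype=np.int64)
    if sidechain_coords is not None:
        pts = np.asarray(sidechain_coords, dtype=np.float64)[:, 4:, :]
        valid = np.isfinite(pts).all(axis=-1)
    else:
        X = structure.backbone_coords
        pts = virtual_cbeta(X[:, 0], X[:, 1], X[:, 2])[:, None, :]
        valid = np.ones((L, 1), dtype=bool)
    d = np.linalg.norm(pts[:, :, None, :] - ctx.coords[None, None, :, :], axis=-1)
    d = np.where(valid[:, :, None], d, np.inf)
    within = (d <= radius).any(axis=(1, 2))
    return np.where(within)[0]


def sequence_recovery(designs: list[np.ndarray], native: np.ndarray,
                      positions: np.ndarray) -> float:
    """Fraction of designed tokens matching the native sequence, averaged
    over designs and restricted to ``positions``."""
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0 or not designs:
        return float("nan")
    native = np.asarray(native)
    matches = [np.mean(np.asarray(d)[positions] == native[positions])
               for d in designs]
    return float(np.mean(matches))


def median_recovery(per_protein: list[float]) -> float:
    vals = [v for v in per_protein if np.isfinite(v)]
    return float(np.median(vals)) if vals else float("nan")


def chi_recovery(predicted_chi: np.ndarray, native_chi: np.ndarray,
                 chi_mask: np.ndarray, sequence: np.ndarray,
                 threshold_deg: float = 10.0,
                 positions: np.ndarray | None = None) -> np.ndarray:
    """Fraction of chis within ``threshold_deg`` of native, per chi index.

    Uses the smallest circular difference; for the 180-degree-symmetric
    terminal chis (ASP/GLU/PHE/TYR) the flipped angle also counts.
    """
    predicted_chi = np.asarray(predicted_chi, dtype=np.float64)
    native_chi = np.asarray(native_chi, dtype=np.float64)
    mask = np.asarray(chi_mask, dtype=bool) & np.isfinite(predicted_chi) \
        & np.isfinite(native_chi)
    if positions is not None:
        keep = np.zeros(mask.shape[0], dtype=bool)
        keep[np.asarray(positions, dtype=np.int64)] = True
        mask = mask & keep[:, None]
    diff = np.abs(wrap_angle(predicted_chi - native_chi))
    for i, tok in enumerate(np.asarray(sequence)):
        three = TOKEN_TO_THREE[int(tok)]
        sym = SYMMETRIC_CHI.get(three)
        if sym is not None:
            k = sym - 1
            flipped = np.abs(wrap_angle(predicted_chi[i, k] - native_chi[i, k] + np.pi))
            diff[i, k] = min(diff[i, k], flipped)
    thresh = np.deg2rad(threshold_deg)
    out = np.full(4, np.nan)
    for k in range(4):
        if mask[:, k].any():
            out[k] = float((diff[mask[:, k], k] <= thresh).mean())
    return out


def confidence_calibration(confidences: np.ndarray,
                           recoveries: np.ndarray) -> tuple[float, bool]:
    """Spearman rank correlation of confidence vs recovery.

    Returns (rho, defined); a constant input makes the correlation undefined
    and is flagged instead of silently returning a number.
    """
    confidences = np.asarray(confidences, dtype=np.float64)
    recoveries = np.asarray(recoveries, dtype=np.float64)
    if confidences.size < 2 or np.ptp(confidences) == 0 or np.ptp(recoveries) == 0:
        return float("nan"), False
    rho = stats.spearmanr(confidences, recoveries).statistic
    return float(rho), True


def metrics_frame(records: list[dict]) -> pd.DataFrame:
    """Tidy metrics table: protein id, category, metric, value."""
    return pd.DataFrame(records, columns=["protein", "category", "metric", "value"])


@dataclass
class EvalReport:
    """Aggregated evaluation: per-protein context-shell recovery (with its
    category), per-chi recovery fractions, and confidence/recovery pairs."""

    recovery: dict[str, float] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)
    chi_fractions: dict[str, np.ndarray] = field(default_factory=dict)
    confidence: dict[str, float] = field(default_factory=dict)

    def add_protein(self, protein: str, category: str, recovery: float,
                    confidence: float = float("nan"),
                    chi_fractions: np.ndarray | None = None) -> None:
        self.recovery[protein] = float(recovery)
        self.category[protein] = category
        self.confidence[protein] = float(confidence)
        if chi_fractions is not None:
            self.chi_fractions[protein] = np.asarray(chi_fractions, dtype=float)

    def median_by_category(self) -> dict[str, float]:
        out: dict[str, list[float]] = {}
        for protein, value in self.recovery.items():
            out.setdefault(self.category[protein], []).append(value)
        return {cat: median_recovery(vals) for cat, vals in out.items()}

    def calibration(self) -> tuple[float, bool]:
        proteins = sorted(self.recovery)
        return confidence_calibration(
            np.array([self.confidence[p] for p in proteins]),
            np.array([self.recovery[p] for p in proteins]))

    def to_frame(self) -> pd.DataFrame:
        records = []
        for protein in sorted(self.recovery):
            cat = self.category[protein]
            records.append({"protein": protein, "category": cat,
                            "metric": "recovery",
                            "value": self.recovery[protein]})
            records.append({"protein": protein, "category": cat,
                            "metric": "confidence",
                            "value": self.confidence[protein]})
            if protein in self.chi_fractions:
                for k, frac in enumerate(self.chi_fractions[protein], start=1):
                    records.append({"protein": protein, "category": cat,
                                    "metric": f"chi{k}_recovery",
                                    "value": float(frac)})
        return metrics_frame(records)
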
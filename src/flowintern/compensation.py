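"""Spillover estimation from single-stain controls and its inverse correction.

The spillover matrix S has unit diagonal; S[i, j] is the fraction of
channel-i signal appearing in channel j.  Estimation uses the median ratio of
secondary to primary totals over positive control events (robust to noise);
compensation right-multiplies observed per-cell intensity vectors by S⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class InsufficientControlError(ValueError):
    """Raised when a single-stain control has too few positive events."""


@dataclass
class SpilloverMatrix:
    labels: tuple[str, ...]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.S = np.asarray(self.S, dtype=float)
        k = len(self.labels)
        if self.S.shape != (k, k):
            raise ValueError("spillover matrix shape does not match labels")
        if not np.allclose(np.diag(self.S), 1.0):
            raise ValueError("spillover diagonal must be exactly 1")
        if (self.S < 0).any():
            raise ValueError("spillover entries must be nonnegative")
        if abs(np.linalg.det(self.S)) < 1e-12:
            raise ValueError("spillover matrix is singular")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.S, index=list(self.labels), columns=list(self.labels)).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.columns), df.to_numpy(dtype=float))


def estimate_spillover(
    controls: dict[str, pd.DataFrame],
    min_positive: int = 20,
) -> SpilloverMatrix:
    """Estimate S from single-stain control totals.

    ``controls`` maps each channel label to a table of per-cell totals whose
    columns include every channel label.  Positive events are those whose
    primary-channel total exceeds the control's background estimate (mean of
    the lowest quartile) plus 3 of its SDs; S[i, j] is the median over
    positives of the channel-j / channel-i total ratio.
    """
    labels = tuple(controls)
    k = len(labels)
    S = np.eye(k)
    for i, lab in enumerate(labels):
        df = controls[lab]
        missing = [c for c in labels if c not in df.columns]
        if missing:
            raise ValueError(f"control {lab!r} lacks columns {missing}")
        primary = df[lab].to_numpy(dtype=float)
        if primary.size == 0:
            raise InsufficientControlError(f"control {lab!r} is empty")
        low = np.sort(primary)[: max(1, primary.size // 4)]
        thr = low.mean() + 3.0 * low.std()
        positive = primary > max(thr, 0.0)
        # all-positive controls: the low-quartile "background" is itself signal
        if positive.sum() < min_positive and (primary > 0).sum() >= min_positive:
            positive = primary > 0
        if positive.sum() < min_positive:
            raise InsufficientControlError(
                f"control {lab!r}: {int(positive.sum())} positive events < {min_positive}"
            )
        for j, other in enumerate(labels):
            if i == j:
                continue
            ratio = df[other].to_numpy(dtype=float)[positive] / primary[positive]
            S[i, j] = max(float(np.median(ratio)), 0.0)
    return SpilloverMatrix(labels, S)


def totals_table(records, channel_labels: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-cell background-subtracted totals, one column per channel label.

    Convenience bridge from a gallery to the ``estimate_spillover`` input.
    """
    from .features import compute_feature_table

    channel_labels = channel_labels or {"compound": 2, "viability": 3}
    feats = compute_feature_table(records)
    return pd.DataFrame(
        {lab: feats[f"total_ch{ch}"] for lab, ch in channel_labels.items()}
    ).dropna()


def apply_compensation(intensities: np.ndarray, spill: SpilloverMatrix) -> np.ndarray:
    """Unmix observed per-cell channel totals: compensated = observed · S⁻¹.

    ``intensities`` is a length-k vector or (n, k) matrix of row vectors in
    the matrix's label order.
    """
    X = np.asarray(intensities, dtype=float)
    k = len(spill.labels)
    if X.shape[-1] != k:
        raise ValueError(f"expected vectors of length {k}, got {X.shape[-1]}")
    return X @ np.linalg.inv(spill.S)
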
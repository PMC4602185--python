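"""Position-specific amino-acid occupancy along the exit-tunnel window.

For every complete USR the tunnel positions are numbered j = 1 (the codon
immediately upstream of the peak, P-site proximal) to j = 31 (most distal).
probs(a, j) is the fraction of USRs with amino acid a at position j, so each
column sums to 1; rows are centred per amino acid for display, and entries
are flagged high/low against the randomized-peak null (or, alternatively,
against the within-row percentile spread).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AA_INDEX, AMINO_ACIDS, InputError, Peak
from .peaks import DEFAULT_TUNNEL_WINDOW


@dataclass
class PositionalMatrix:
    """20 x window matrices of tunnel-position occupancy probabilities."""

    probs: np.ndarray
    n_usrs: int
    standardized: np.ndarray | None = None
    flags: np.ndarray | None = None  # strings in {"", "high", "low"}

    @property
    def window(self) -> int:
        return self.probs.shape[1]

    def _frame(self, m: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(m, index=pd.Index(AMINO_ACIDS, name="amino_acid"),
                            columns=[f"pos_{j}" for j in range(1, self.window + 1)])

    def probs_frame(self) -> pd.DataFrame:
        return self._frame(self.probs)

    def standardized_frame(self) -> pd.DataFrame:
        if self.standardized is None:
            raise InputError("standardized matrix not computed")
        return self._frame(self.standardized)

    def flags_frame(self) -> pd.DataFrame:
        if self.flags is None:
            raise InputError("flags not computed")
        return self._frame(self.flags)

    def plot_heatmap(self, ax=None):
        """Heatmap of the standardized matrix (matplotlib; lazy import)."""
        import matplotlib.pyplot as plt

        if self.standardized is None:
            raise InputError("standardized matrix not computed")
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 6))
        im = ax.imshow(self.standardized, aspect="auto", cmap="RdBu_r")
        ax.set_yticks(range(20), AMINO_ACIDS)
        ax.set_xticks(range(0, self.window, 5),
                      [str(j + 1) for j in range(0, self.window, 5)])
        ax.set_xlabel("tunnel position (1 = P-site proximal)")
        ax.set_ylabel("amino acid")
        ax.figure.colorbar(im, ax=ax, label="probability - row mean")
        return ax


def usr_position_counts(usrs: list[str], window: int = DEFAULT_TUNNEL_WINDOW) -> np.ndarray:
    """(20, window) occupancy counts; position j is usr[-j]."""
    counts = np.zeros((20, window), dtype=np.int64)
    for usr in usrs:
        if len(usr) != window:
            raise InputError(f"USR of length {len(usr)}; expected {window}")
        for j in range(1, window + 1):
            a = AA_INDEX.get(usr[-j])
            if a is not None:
                counts[a, j - 1] += 1
    return counts


def positional_probabilities(peaks: list[Peak],
                             window: int = DEFAULT_TUNNEL_WINDOW) -> PositionalMatrix:
    """Occupancy probabilities over all complete USRs; errors with no peaks."""
    usrs = [p.usr for p in peaks if p.usr_complete and p.usr]
    if not usrs:
        raise InputError("positional_probabilities: no complete USRs")
    counts = usr_position_counts(usrs, window)
    return PositionalMatrix(probs=counts / len(usrs), n_usrs=len(usrs))


def standardize(m: PositionalMatrix) -> PositionalMatrix:
    """Centre each amino-acid row to mean zero (idempotent on the output)."""
    m.standardized = m.probs - m.probs.mean(axis=1, keepdims=True)
    return m


def flag_extreme_positions(m: PositionalMatrix, null_counts: np.ndarray,
                           alpha: float = 0.05) -> PositionalMatrix:
    """Two-sided empirical flags against the randomized-peak null.

    ``null_counts`` is the (N, 20, window) occupancy of random USR sets (same
    number of peaks). Entry (a, j) is flagged high when
    #{null >= observed} / N <= alpha/2, low when #{null <= observed} / N <=
    alpha/2.
    """
    null_probs = null_counts / m.n_usrs
    p_high = np.mean(null_probs >= m.probs[None, :, :], axis=0)
    p_low = np.mean(null_probs <= m.probs[None, :, :], axis=0)
    flags = np.full(m.probs.shape, "", dtype=object)
    flags[p_high <= alpha / 2] = "high"
    flags[p_low <= alpha / 2] = "low"
    m.flags = flags
    return m


def flag_row_percentile(m: PositionalMatrix, alpha: float = 0.05) -> PositionalMatrix:
    """Alternative flagging: compare each entry to the other positions of its
    own row (strictly above/below the row's 1-alpha/2 and alpha/2 quantiles)."""
    lo = np.quantile(m.probs, alpha / 2, axis=1, keepdims=True)
    hi = np.quantile(m.probs, 1 - alpha / 2, axis=1, keepdims=True)
    flags = np.full(m.probs.shape, "", dtype=object)
    flags[m.probs > hi] = "high"
    flags[m.probs < lo] = "low"
    m.flags = flags
    return m
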
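"""Sequence-level features of Reb homologs.

* :func:`conservation_profile` — per-column residue frequencies and Shannon
  information content (bits) of a multiple alignment, the quantitative core
  of a sequence logo.  Gaps are excluded from the frequency denominator and
  reported separately; columns with more than half gaps are flagged.

* :func:`hydrophobic_moment` — the Eisenberg hydrophobic moment µH on an
  idealized α-helix (one residue every ``delta_deg``, default 100°), the
  quantity a helical-wheel diagram visualizes.  High µH over a window means
  hydrophobic residues concentrate on one helix face (amphipathicity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import AMINO_ACIDS

MAX_BITS = math.log2(20)

#: Eisenberg consensus hydrophobicity scale.
EISENBERG_SCALE: Dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column frequency vectors + information content of an alignment."""

    frequencies: np.ndarray      # (alignment_length, 20), rows sum to 1 or 0
    information: np.ndarray      # bits, per column
    gap_fraction: np.ndarray     # per column
    n_sequences: int

    @property
    def alignment_length(self) -> int:
        return self.frequencies.shape[0]

    @property
    def high_gap_columns(self) -> np.ndarray:
        """Indices of columns with more than 50% gaps."""
        return np.flatnonzero(self.gap_fraction > 0.5)

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table: column, top residue(s), bits, gap fraction."""
        rows = []
        for i in range(self.alignment_length):
            freqs = self.frequencies[i]
            order = np.argsort(-freqs, kind="stable")
            top = [
                f"{AMINO_ACIDS[j]}:{freqs[j]:.2f}"
                for j in order[:3]
                if freqs[j] > 0
            ]
            rows.append(
                {
                    "column": i,
                    "top_residues": ",".join(top),
                    "information_bits": round(float(self.information[i]), 4),
                    "gap_fraction": round(float(self.gap_fraction[i]), 4),
                    "high_gap": bool(self.gap_fraction[i] > 0.5),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["column", "top_residues", "information_bits",
                     "gap_fraction", "high_gap"],
        )


def conservation_profile(aligned: Sequence[str]) -> ConservationProfile:
    """Column conservation of an aligned set of sequences.

    All sequences must have equal length (a ragged input raises).  Per
    column, frequencies run over the 20 standard residues among non-gap,
    non-X characters; information = log2(20) − Shannon entropy in bits (no
    small-sample correction).  A column with no countable residues carries
    0 bits.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 aligned sequences")
    length = len(aligned[0])
    for i, seq in enumerate(aligned):
        if len(seq) != length:
            raise ValueError(
                f"ragged alignment: sequence {i} has length {len(seq)}, "
                f"expected {length}"
            )
    aa_index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    n = len(aligned)
    counts = np.zeros((length, 20), dtype=float)
    gaps = np.zeros(length, dtype=float)
    for seq in aligned:
        for col, ch in enumerate(seq.upper()):
            if ch in GAP_CHARS:
                gaps[col] += 1.0
            elif ch in aa_index:
                counts[col, aa_index[ch]] += 1.0
            elif ch == "X":
                pass  # unknown residue: not a gap, not countable
            else:
                raise ValueError(f"unexpected character {ch!r} in alignment")
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts)
    nonzero = totals > 0
    freqs[nonzero] = counts[nonzero] / totals[nonzero, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    information = np.where(nonzero, MAX_BITS - entropy, 0.0)
    return ConservationProfile(
        frequencies=freqs,
        information=information,
        gap_fraction=gaps / n,
        n_sequences=n,
    )


@dataclass(frozen=True)
class AmphipathicityResult:
    """Hydrophobic moment of one helical window of one sequence."""

    sequence_id: str
    window: Tuple[int, int]          # (start, end) 0-based half-open
    mean_hydrophobicity: float
    hydrophobic_moment: float        # µH per residue, >= 0
    rotation_angle_deg: float

    def __post_init__(self) -> None:
        if self.hydrophobic_moment < 0:
            raise ValueError("µH must be >= 0")


def hydrophobic_moment(
    sequence: str,
    window_len: int = 18,
    scale: Mapping[str, float] = EISENBERG_SCALE,
    delta_deg: float = 100.0,
    sequence_id: str = "seq",
) -> List[AmphipathicityResult]:
    """Sliding-window helical hydrophobic moment.

    µH = (1/N) * || Σ_n h_n (cos nδ, sin nδ) || for each length-``window_len``
    window, sliding by one residue.  δ = 100° is the canonical α-helix twist
    (3.6 residues/turn).  Residues missing from the scale raise.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if window_len > len(sequence):
        raise ValueError(
            f"window_len {window_len} exceeds sequence length {len(sequence)}"
        )
    try:
        h = np.array([scale[aa] for aa in sequence], dtype=float)
    except KeyError as exc:
        raise KeyError(
            f"{sequence_id}: residue {exc.args[0]!r} has no hydrophobicity "
            "scale entry"
        ) from None
    delta = math.radians(delta_deg)
    angles = delta * np.arange(len(sequence))
    cx, sx = np.cos(angles), np.sin(angles)
    results = []
    for start in range(len(sequence) - window_len + 1):
        end = start + window_len
        hw = h[start:end]
        # phase within the window restarts at n=0 (global rotation is
        # irrelevant to the magnitude, so reuse the precomputed phases)
        vx = float(np.dot(hw, cx[start:end]))
        vy = float(np.dot(hw, sx[start:end]))
        mu = math.hypot(vx, vy) / window_len
        results.append(
            AmphipathicityResult(
                sequence_id=sequence_id,
                window=(start, end),
                mean_hydrophobicity=float(hw.mean()),
                hydrophobic_moment=mu,
                rotation_angle_deg=delta_deg,
            )
        )
    return results


def max_amphipathicity(
    sequence: str,
    window_len: int = 18,
    scale: Mapping[str, float] = EISENBERG_SCALE,
    delta_deg: float = 100.0,
    sequence_id: str = "seq",
) -> AmphipathicityResult:
    """The maximum-µH window of a sequence (ties toward the earliest)."""
    results = hydrophobic_moment(
        sequence, window_len=window_len, scale=scale,
        delta_deg=delta_deg, sequence_id=sequence_id,
    )
    return max(results, key=lambda r: (r.hydrophobic_moment, -r.window[0]))


def moment_table(
    sequences: Mapping[str, str],
    window_len: int = 18,
    scale: Mapping[str, float] = EISENBERG_SCALE,
    delta_deg: float = 100.0,
) -> pd.DataFrame:
    """Best-window µH per sequence, TSV-ready."""
    rows = []
    for seq_id in sorted(sequences):
        seq = sequences[seq_id]
        if len(seq) < window_len:
            continue
        best = max_amphipathicity(
            seq, window_len=window_len, scale=scale,
            delta_deg=delta_deg, sequence_id=seq_id,
        )
        rows.append(
            {
                "sequence_id": seq_id,
                "window_start": best.window[0],
                "window_end": best.window[1],
                "muH": round(best.hydrophobic_moment, 4),
                "meanH": round(best.mean_hydrophobicity, 4),
            }
        )
    return pd.DataFrame(
        rows, columns=["sequence_id", "window_start", "window_end", "muH", "meanH"]
    )
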
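"""Consensus and entropy-scaled sequence-logo statistics for aligned
S4-helix sequences.

Column frequencies are computed over the 20 amino acids with gaps excluded
from the normalisation (configurable). Shannon entropy H = −Σ p log2 p is
reported in bits; the default stack height is the information content
log2(20) − H, the standard logo convention. A literal "inverse entropy" mode
(height = c/(H+ε)) is provided as well, with a small ε so perfectly conserved
columns stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = {"-", ".", "~"}
MAX_ENTROPY_BITS = math.log2(20)


@dataclass
class AlignmentColumn:
    position: int                 # zero-based column index
    frequencies: dict             # residue -> fraction (gaps excluded by default)
    gap_fraction: float
    n_sequences: int
    entropy: float                # bits
    stack_height: float
    height_mode: str = "information"


def read_alignment(path):
    """Aligned FASTA -> list of (id, sequence) with equal lengths enforced."""
    aln = AlignIO.read(str(path), "fasta")
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def _columns(msa):
    if not msa:
        raise ValueError("alignment is empty")
    seqs = [s for _, s in msa] if isinstance(msa[0], tuple) else list(msa)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences differ in length")
    return seqs, lengths.pop()


def column_stats(msa, position: int, include_gaps: bool = False,
                 height_mode: str = "information", epsilon: float = 0.1
                 ) -> AlignmentColumn:
    """Frequencies, Shannon entropy and logo stack height for one column.

    ``msa`` is a list of sequences or (id, sequence) pairs of equal length
    (e.g. from :func:`read_alignment`). ``height_mode`` is "information"
    (log2 20 − H) or "inverse_entropy" (MAX_ENTROPY/(H + ε)).
    """
    seqs, length = _columns(msa)
    if not 0 <= position < length:
        raise IndexError(f"column {position} outside alignment of length {length}")
    letters = [s[position] for s in seqs]
    gaps = sum(1 for c in letters if c in GAP_CHARS)
    residues = [c for c in letters if c not in GAP_CHARS]
    denom = len(letters) if include_gaps else len(residues)
    freqs = {}
    if denom:
        for aa in sorted(set(residues)):
            freqs[aa] = residues.count(aa) / denom
    probs = np.array([f for f in freqs.values() if f > 0])
    # normalise over observed residues for the entropy when gaps are included
    if probs.size:
        p = probs / probs.sum() if include_gaps else probs
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = float("nan")
    if height_mode == "information":
        height = MAX_ENTROPY_BITS - entropy if math.isfinite(entropy) else 0.0
    elif height_mode == "inverse_entropy":
        height = MAX_ENTROPY_BITS / (entropy + epsilon) \
            if math.isfinite(entropy) else 0.0
    else:
        raise ValueError(f"unknown height mode '{height_mode}'")
    return AlignmentColumn(position=position, frequencies=freqs,
                           gap_fraction=gaps / len(letters),
                           n_sequences=len(letters), entropy=entropy,
                           stack_height=height, height_mode=height_mode)


def logo_table(msa, **kwargs) -> pd.DataFrame:
    """Per-column logo statistics for a whole alignment (CSV-ready)."""
    seqs, length = _columns(msa)
    rows = []
    for pos in range(length):
        col = column_stats(msa, pos, **kwargs)
        top = max(col.frequencies, key=col.frequencies.get) \
            if col.frequencies else "-"
        rows.append({"position": pos, "entropy_bits": col.entropy,
                     "stack_height": col.stack_height,
                     "gap_fraction": col.gap_fraction,
                     "top_residue": top,
                     "top_frequency": col.frequencies.get(top, 0.0)})
    return pd.DataFrame(rows)


@dataclass
class ConsensusPosition:
    residue: str
    frequency: float
    tie: bool = False


def consensus(msa):
    """Modal residue per column, ties broken alphabetically and flagged.

    Returns (consensus string, list of ConsensusPosition).
    """
    seqs, length = _columns(msa)
    positions = []
    for pos in range(length):
        letters = [s[pos] for s in seqs if s[pos] not in GAP_CHARS]
        if not letters:
            positions.append(ConsensusPosition("-", 0.0))
            continue
        counts = {}
        for c in letters:
            counts[c] = counts.get(c, 0) + 1
        best_count = max(counts.values())
        winners = sorted(c for c, n in counts.items() if n == best_count)
        positions.append(ConsensusPosition(
            winners[0], best_count / len(letters), tie=len(winners) > 1))
    return "".join(p.residue for p in positions), positions
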
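"""Composition and accumulative-position vectors (FDV, AAPIV, RAAPIV).

Three length-4 vectors per sequence, components ordered (A, C, G, T):

* FDV  — occurrence counts of each nucleotide; components sum to the
  sequence length.
* AAPIV — per-nucleotide sums of 1-based occurrence positions; components
  sum to n(n+1)/2 since every position is counted exactly once.
* RAAPIV — AAPIV of the reversed residue string.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import NucleotideSequence

NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class PositionalVectors:
    fdv: np.ndarray
    aapiv: np.ndarray
    raapiv: np.ndarray


def _residues(seq: NucleotideSequence | str) -> str:
    return seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()


def fdv(seq: NucleotideSequence | str, normalize: bool = False) -> np.ndarray:
    """Occurrence counts of (A, C, G, T); optionally divided by length."""
    residues = _residues(seq)
    counts = np.array([residues.count(n) for n in NUCLEOTIDES], dtype=float)
    return counts / len(residues) if normalize else counts


def aapiv(seq: NucleotideSequence | str) -> np.ndarray:
    """Per-nucleotide sums of 1-based occurrence positions, order (A, C, G, T)."""
    residues = _residues(seq)
    out = np.zeros(4, dtype=float)
    lut = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for pos, r in enumerate(residues, start=1):
        out[lut[r]] += pos
    return out


def raapiv(seq: NucleotideSequence | str) -> np.ndarray:
    """AAPIV computed on the reversed residue string."""
    return aapiv(_residues(seq)[::-1])


def positional_vectors(
    seq: NucleotideSequence | str, normalize_fdv: bool = False
) -> PositionalVectors:
    return PositionalVectors(
        fdv=fdv(seq, normalize=normalize_fdv),
        aapiv=aapiv(seq),
        raapiv=raapiv(seq),
    )
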
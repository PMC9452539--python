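"""Position-relative incidence matrices (PRIM / RPRIM).

For a sequence tokenized into overlapping k-mers at 1-based positions, the
incidence matrix entry N(x -> y) accumulates, for every occurrence of the
target symbol y at position p, the signed offset p - f(x) from the first
occurrence f(x) of the reference symbol x.  Rows are reference symbols,
columns target symbols, both in lexicographic order (A < C < G < T,
extended to k-mers); a row whose reference symbol never occurs is all
zeros.  The reverse-direction matrix (RPRIM) applies the same rule to the
reversed residue string.

Mono-, di- and tri-nucleotide orders give 4x4, 16x16 and 64x64 matrices.
The feature pipeline uses the order-1 forward and reverse matrices, each
summarised by its 30-moment block (raw, central, Hahn); higher orders are
built for dataset-level heatmap tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Literal

import numpy as np
import pandas as pd

from .moments import HahnParams, SquareMatrix, moment_block
from .sequence_io import LabeledDataset, NucleotideSequence

Direction = Literal["forward", "reverse"]


def kmer_alphabet(order: int) -> list[str]:
    """All 4**order k-mers in lexicographic order."""
    return ["".join(p) for p in product("ACGT", repeat=order)]


@dataclass(frozen=True)
class PRIMMatrix:
    """An incidence matrix together with its order and direction."""

    order: int
    direction: Direction
    entries: np.ndarray

    @property
    def alphabet(self) -> list[str]:
        return kmer_alphabet(self.order)

    def as_frame(self) -> pd.DataFrame:
        alpha = self.alphabet
        return pd.DataFrame(self.entries, index=alpha, columns=alpha)


def prim_matrix(
    seq: NucleotideSequence | str,
    order: int = 1,
    direction: Direction = "forward",
) -> PRIMMatrix:
    """Incidence matrix of signed positional offsets relative to first occurrences."""
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq.upper()
    if len(residues) < order:
        raise ValueError(
            f"sequence of length {len(residues)} shorter than k-mer order {order}"
        )
    if direction == "reverse":
        residues = residues[::-1]
    elif direction != "forward":
        raise ValueError(f"unknown direction {direction!r}")

    alpha = kmer_alphabet(order)
    index = {sym: i for i, sym in enumerate(alpha)}
    tokens = [residues[i : i + order] for i in range(len(residues) - order + 1)]

    n = len(alpha)
    first = np.full(n, -1, dtype=np.int64)  # 1-based first occurrence, -1 = absent
    # position-sum and count per target symbol, for vectorised offset sums
    pos_sum = np.zeros(n, dtype=np.int64)
    count = np.zeros(n, dtype=np.int64)
    for p, tok in enumerate(tokens, start=1):
        t = index[tok]
        if first[t] < 0:
            first[t] = p
        pos_sum[t] += p
        count[t] += 1

    # entry(x, y) = sum_p (p - f(x)) over occurrences p of y = pos_sum[y] - f(x)*count[y]
    entries = np.zeros((n, n), dtype=float)
    present = first >= 0
    entries[present, :] = pos_sum[None, :] - np.outer(first[present], count)
    return PRIMMatrix(order, direction, entries)


def prim_moment_block(
    seq: NucleotideSequence | str,
    hahn_params: HahnParams | None = None,
) -> np.ndarray:
    """60 features: 30-moment block of the forward order-1 PRIM, then of the RPRIM."""
    fwd = prim_matrix(seq, order=1, direction="forward")
    rev = prim_matrix(seq, order=1, direction="reverse")
    return np.concatenate(
        [
            moment_block(SquareMatrix(fwd.entries), hahn_params),
            moment_block(SquareMatrix(rev.entries), hahn_params),
        ]
    )


def prim_heatmap_table(
    dataset: LabeledDataset,
    order: int = 1,
    direction: Direction = "forward",
) -> pd.DataFrame:
    """Elementwise sum of per-sequence incidence matrices over a dataset.

    The labelled table is the numeric basis for composition heatmaps.
    """
    if len(dataset) == 0:
        raise ValueError("cannot summarise an empty dataset")
    total = None
    for seq in dataset.sequences:
        m = prim_matrix(seq, order=order, direction=direction).entries
        total = m if total is None else total + m
    alpha = kmer_alphabet(order)
    return pd.DataFrame(total, index=alpha, columns=alpha)
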
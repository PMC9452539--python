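"""Synthetic two-layer sequence sets with controllable class separation.

Sequences are drawn i.i.d. per position from class-specific nucleotide
distributions.  Non-enhancers use the uniform distribution (0.25 each).
Enhancer classes shift probability mass from A/T toward C/G, mimicking the
GC-richness of regulatory regions: with per-nucleotide shift s, the
distribution is (0.25-s, 0.25+s, 0.25+s, 0.25-s) over (A, C, G, T).
Strong enhancers use s = effect/4 and weak enhancers s = effect/8, so the
two strengths differ by a further effect/8 shift and, at effect = 1, the
strong class reaches the maximally divergent distribution (0, .5, .5, 0)
while all probabilities stay in [0, 1].  effect = 0 collapses every class
onto the uniform distribution.

Class sizes default to the benchmark layout: 742 strong + 742 weak
enhancers against 1484 non-enhancers, 200 bp each.

``worked_examples`` returns the tiny hand-checkable sequences used across
the unit tests together with their expected positional vectors, incidence
rows and reshapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import numpy as np

from .sequence_io import (
    ENHANCER,
    NON_ENHANCER,
    STRONG,
    WEAK,
    LabeledDataset,
    NucleotideSequence,
    write_dataset,
)

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationSpec:
    """Generator conditions for one synthetic two-layer dataset.

    ``n_per_class`` is the layer-1 class size (enhancers split evenly into
    strong and weak); ``effect`` in [0, 1] controls compositional
    divergence between classes.
    """

    n_per_class: int = 1484
    length: int = 200
    effect: float = 0.6
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.length < 4:
            raise ValueError("length must be >= 4")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")


def class_distributions(effect: float) -> dict[str, np.ndarray]:
    """Per-class nucleotide probabilities over (A, C, G, T)."""

    def shifted(s: float) -> np.ndarray:
        return np.array([0.25 - s, 0.25 + s, 0.25 + s, 0.25 - s])

    return {
        NON_ENHANCER: shifted(0.0),
        WEAK: shifted(effect / 8),
        STRONG: shifted(effect / 4),
    }


def simulate_dataset(spec: SimulationSpec) -> LabeledDataset:
    """Draw a labelled dataset; identical output for identical specs."""
    rng = np.random.default_rng(spec.seed)
    dists = class_distributions(spec.effect)
    n_strong = spec.n_per_class // 2
    n_weak = spec.n_per_class - n_strong

    sequences: list[NucleotideSequence] = []
    layer1: list[str] = []
    layer2: list[str | None] = []
    plan = [
        (STRONG, n_strong, ENHANCER, STRONG),
        (WEAK, n_weak, ENHANCER, WEAK),
        (NON_ENHANCER, spec.n_per_class, NON_ENHANCER, None),
    ]
    for dist_key, count, l1, l2 in plan:
        p = dists[dist_key]
        draws = rng.choice(4, size=(count, spec.length), p=p)
        for i in range(count):
            residues = "".join(NUCLEOTIDES[draws[i]])
            sequences.append(NucleotideSequence(f"{dist_key}_{i:05d}", residues))
            layer1.append(l1)
            layer2.append(l2)
    return LabeledDataset(sequences, layer1, layer2)


def simulate_to_fasta(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate and write class-separated FASTA files (load_dataset layout)."""
    return write_dataset(simulate_dataset(spec), outdir)


@dataclass(frozen=True)
class WorkedExample:
    """A tiny sequence with hand-computed expected feature values."""

    sequence: str
    fdv: tuple[int, ...]
    aapiv: tuple[int, ...]
    raapiv: tuple[int, ...]
    reshape_rows: tuple[tuple[int, ...], ...] | None = None
    prim_rows: Mapping[str, tuple[float, ...]] | None = None


_WORKED: dict[str, WorkedExample] = {
    "ACGT": WorkedExample(
        sequence="ACGT",
        fdv=(1, 1, 1, 1),
        aapiv=(1, 2, 3, 4),
        raapiv=(4, 3, 2, 1),
        reshape_rows=((1, 2), (3, 4)),
    ),
    "AACG": WorkedExample(
        sequence="AACG",
        fdv=(2, 1, 1, 0),
        aapiv=(3, 3, 4, 0),
        raapiv=(7, 2, 1, 0),
        prim_rows=MappingProxyType(
            {"A": (1.0, 2.0, 3.0, 0.0), "C": (-3.0, 0.0, 1.0, 0.0),
             "T": (0.0, 0.0, 0.0, 0.0)}
        ),
    ),
    "AAAA": WorkedExample(
        sequence="AAAA",
        fdv=(4, 0, 0, 0),
        aapiv=(10, 0, 0, 0),
        raapiv=(10, 0, 0, 0),
        prim_rows=MappingProxyType({"A": (6.0, 0.0, 0.0, 0.0)}),
    ),
    "ATTA": WorkedExample(
        sequence="ATTA",
        fdv=(2, 0, 0, 2),
        aapiv=(5, 0, 0, 5),
        raapiv=(5, 0, 0, 5),
    ),
    "ACGTACGTA": WorkedExample(
        sequence="ACGTACGTA",
        fdv=(3, 2, 2, 2),
        aapiv=(15, 8, 10, 12),
        raapiv=(15, 12, 10, 8),
        reshape_rows=((1, 2, 3), (4, 1, 2), (3, 4, 1)),
    ),
    "ACGT50": WorkedExample(
        sequence="ACGT" * 50,
        fdv=(50, 50, 50, 50),
        aapiv=(4950, 5000, 5050, 5100),
        raapiv=(5100, 5050, 5000, 4950),
    ),
}


def worked_examples() -> Mapping[str, WorkedExample]:
    """Immutable set of hand-checkable regression sequences."""
    return MappingProxyType(_WORKED)
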
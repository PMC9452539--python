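"""Assembly of the 102-dimensional super feature vector and feature tables.

Fixed block layout per sequence:

    seq_moments[30] | prim_moments[30] | rprim_moments[30]
    | fdv[4] | aapiv[4] | raapiv[4]

Each 30-block is raw(10) | central(10) | Hahn(10), with each 10-vector in
the (00, 01, 10, 11, 02, 20, 12, 21, 30, 03) index order.  The block
boundaries (30, 60, 90, 94, 98, 102) are part of the public contract.

Every numeric choice the moments depend on — the nucleotide encoding and
the Hahn shape parameters — travels with the extracted table as
provenance, written as commented header lines in the TSV serialization.
No scaling is applied: the downstream forest is scale-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .moments import (
    DEFAULT_ENCODING,
    HahnParams,
    MOMENT_INDEX_ORDER,
    encode,
    moment_block,
    reshape_to_square,
)
from .positional import NUCLEOTIDES, aapiv, fdv, raapiv
from .prim import prim_moment_block
from .sequence_io import LabeledDataset, NucleotideSequence

SFV_LENGTH = 102

#: Half-open [start, stop) column ranges of the named blocks.
BLOCK_SLICES: dict[str, tuple[int, int]] = {
    "seq_moments": (0, 30),
    "prim_moments": (30, 60),
    "rprim_moments": (60, 90),
    "fdv": (90, 94),
    "aapiv": (94, 98),
    "raapiv": (98, 102),
}


def _moment_names(prefix: str) -> list[str]:
    return [
        f"{prefix}_{kind}_{j}{k}"
        for kind in ("raw", "central", "hahn")
        for j, k in MOMENT_INDEX_ORDER
    ]


#: The 102 column names, in layout order.
FEATURE_NAMES: list[str] = (
    _moment_names("seq")
    + _moment_names("prim")
    + _moment_names("rprim")
    + [f"fdv_{n}" for n in NUCLEOTIDES]
    + [f"aapiv_{n}" for n in NUCLEOTIDES]
    + [f"raapiv_{n}" for n in NUCLEOTIDES]
)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable choices of the extraction stage.

    encoding:      nucleotide -> integer map used for the sequence matrix.
    hahn_x/hahn_y: Hahn polynomial shape parameters (default 0, symmetric).
    normalize_fdv: divide composition counts by sequence length.
    """

    encoding: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ENCODING)
    )
    hahn_x: float = 0.0
    hahn_y: float = 0.0
    normalize_fdv: bool = False

    def provenance(self) -> dict[str, str]:
        enc = ",".join(f"{k}={v}" for k, v in sorted(self.encoding.items()))
        return {
            "software": f"enhmom {__version__}",
            "encoding": enc,
            "hahn_x": str(self.hahn_x),
            "hahn_y": str(self.hahn_y),
            "normalize_fdv": str(self.normalize_fdv),
        }


def super_feature_vector(
    seq: NucleotideSequence | str,
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """The 102 features of one sequence, deterministic given sequence + config."""
    config = config or FeatureConfig()
    if isinstance(seq, str):
        seq = NucleotideSequence("anonymous", seq)
    hahn = HahnParams(N=1, x=config.hahn_x, y=config.hahn_y)  # N rebound per matrix
    try:
        matrix = reshape_to_square(encode(seq, config.encoding))
        vec = np.concatenate(
            [
                moment_block(matrix, hahn),
                prim_moment_block(seq, hahn),
                fdv(seq, normalize=config.normalize_fdv),
                aapiv(seq),
                raapiv(seq),
            ]
        )
    except Exception as exc:
        raise type(exc)(f"sequence {seq.id!r}: {exc}") from exc
    assert vec.shape == (SFV_LENGTH,)
    return vec


@dataclass
class FeatureTable:
    """Per-sequence feature rows with ids, labels and extraction provenance."""

    data: pd.DataFrame  # shape (n, 102), columns FEATURE_NAMES, index = ids
    layer1: list[str]
    layer2: list[Optional[str]]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        if list(self.data.columns) != FEATURE_NAMES:
            raise ValueError("feature table columns do not match the fixed layout")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("feature table contains non-finite values")
        if not (len(self.data) == len(self.layer1) == len(self.layer2)):
            raise ValueError("row/label count mismatch")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy()


def extract_dataset(
    dataset: LabeledDataset,
    config: FeatureConfig | None = None,
) -> FeatureTable:
    """One feature row per sequence, in dataset order; fails fast with the id."""
    if len(dataset) == 0:
        raise ValueError("cannot extract features from an empty dataset")
    config = config or FeatureConfig()
    rows = np.vstack([super_feature_vector(s, config) for s in dataset.sequences])
    data = pd.DataFrame(rows, columns=FEATURE_NAMES, index=dataset.ids)
    return FeatureTable(
        data=data,
        layer1=list(dataset.layer1),
        layer2=list(dataset.layer2),
        provenance=config.provenance(),
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """TSV with '#' provenance header, id/label columns, then the 102 features."""
    out = table.data.copy()
    out.insert(0, "layer2", [l if l is not None else "" for l in table.layer2])
    out.insert(0, "layer1", table.layer1)
    with open(path, "w") as handle:
        for key, value in table.provenance.items():
            handle.write(f"# {key}: {value}\n")
        out.to_csv(handle, sep="\t", index_label="id")


def read_feature_table(path: str | Path) -> FeatureTable:
    provenance: dict[str, str] = {}
    with open(path) as handle:
        pos = handle.tell()
        while True:
            line = handle.readline()
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition(":")
                provenance[key.strip()] = value.strip()
                pos = handle.tell()
            else:
                handle.seek(pos)
                break
        frame = pd.read_csv(handle, sep="\t", index_col="id")
    layer1 = list(frame.pop("layer1"))
    layer2_raw = frame.pop("layer2")
    layer2 = [None if (isinstance(v, float) and np.isnan(v)) or v == "" else v
              for v in layer2_raw]
    return FeatureTable(frame, layer1, layer2, provenance)
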
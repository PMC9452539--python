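"""Reading, validating and labelling DNA sequences.

The benchmark for enhancer identification is organised as a two-layer
dataset: sequences are first enhancers or non-enhancers, and enhancers are
further strong or weak.  Labels are carried by file grouping (one FASTA per
class), or alternatively by a two-column TSV label map for single-file
input.  Only the strict four-letter alphabet A/C/G/T is accepted; ambiguity
codes are rejected, not imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGT")

ENHANCER = "enhancer"
NON_ENHANCER = "non_enhancer"
STRONG = "strong"
WEAK = "weak"
UNKNOWN = "unknown"

MIN_LENGTH = 4


class EmptyInputError(ValueError):
    """Raised when a FASTA file or sequence set contains no records."""


class SequenceValidationError(ValueError):
    """Raised when a record violates the A/C/G/T alphabet or length rule."""


class LabelConflictError(ValueError):
    """Raised when one sequence id carries contradictory labels."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence over the alphabet {A, C, G, T}.

    Residues are stored upper-case.  Length must be at least 4 so that the
    square-matrix reshape and the positional vectors are well defined.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r} contains non-ACGT character(s): "
                f"{', '.join(sorted(bad))}"
            )
        if len(self.residues) < MIN_LENGTH:
            raise SequenceValidationError(
                f"record {self.id!r} has length {len(self.residues)} < {MIN_LENGTH}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse(self) -> "NucleotideSequence":
        """The same residues in reverse order (not reverse complement)."""
        return NucleotideSequence(self.id, self.residues[::-1])


@dataclass
class LabeledDataset:
    """Two-layer labelled sequence collection.

    Layer 1 distinguishes enhancers from non-enhancers; layer 2 subdivides
    enhancers into strong and weak.  Layer-2 labels exist only for
    enhancers; enhancers without a known strength carry ``unknown``.
    """

    sequences: list[NucleotideSequence]
    layer1: list[str]
    layer2: list[Optional[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layer2:
            self.layer2 = [UNKNOWN if l == ENHANCER else None for l in self.layer1]
        if not (len(self.sequences) == len(self.layer1) == len(self.layer2)):
            raise ValueError("sequences and label lists must have equal length")
        for l1, l2 in zip(self.layer1, self.layer2):
            if l1 not in (ENHANCER, NON_ENHANCER):
                raise ValueError(f"invalid layer-1 label {l1!r}")
            if l1 == NON_ENHANCER and l2 is not None:
                raise ValueError("layer-2 label on a non-enhancer")
            if l1 == ENHANCER and l2 not in (STRONG, WEAK, UNKNOWN):
                raise ValueError(f"invalid layer-2 label {l2!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def class_counts(self) -> dict[str, int]:
        counts = {
            ENHANCER: self.layer1.count(ENHANCER),
            NON_ENHANCER: self.layer1.count(NON_ENHANCER),
            STRONG: self.layer2.count(STRONG),
            WEAK: self.layer2.count(WEAK),
        }
        return counts


def _records_to_sequences(
    records: Iterable[SeqRecord],
    policy: Literal["strict", "skip_invalid"],
    source: str,
) -> list[NucleotideSequence]:
    out: list[NucleotideSequence] = []
    skipped = 0
    for rec in records:
        try:
            out.append(NucleotideSequence(rec.id, str(rec.seq)))
        except SequenceValidationError:
            if policy == "strict":
                raise
            skipped += 1
    if skipped:
        logger.warning("%s: skipped %d invalid record(s)", source, skipped)
    return out


def read_fasta(
    path: str | Path,
    policy: Literal["strict", "skip_invalid"] = "strict",
) -> list[NucleotideSequence]:
    """Parse a (possibly line-wrapped) FASTA file into validated sequences.

    Under ``strict`` any record with a character outside A/C/G/T aborts the
    parse with an error naming the record and the offending character;
    under ``skip_invalid`` such records are dropped and counted in a log
    message.  An empty file is an error in either mode.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    if policy not in ("strict", "skip_invalid"):
        raise ValueError(f"unknown policy {policy!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return _records_to_sequences(records, policy, str(path))


def write_fasta(sequences: Sequence[NucleotideSequence], path: str | Path) -> None:
    """Write sequences as single-line FASTA records."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta-2line")


def _check_unique_ids(groups: dict[str, list[NucleotideSequence]]) -> None:
    seen: dict[str, str] = {}
    for group, seqs in groups.items():
        for s in seqs:
            if s.id in seen:
                raise LabelConflictError(
                    f"sequence id {s.id!r} appears in both "
                    f"{seen[s.id]!r} and {group!r} sources"
                )
            seen[s.id] = group


def load_dataset(
    enhancer_source: str | Path | None,
    non_enhancer_source: str | Path,
    strong_source: str | Path | None = None,
    weak_source: str | Path | None = None,
    policy: Literal["strict", "skip_invalid"] = "strict",
) -> LabeledDataset:
    """Build the two-layer dataset from one FASTA file per class.

    Layer-1 labels come from the enhancer / non-enhancer files; layer-2
    labels from the optional strong / weak files, matched by sequence id
    against the enhancer file.  If ``enhancer_source`` is None, the strong
    and weak files together define the enhancer class.  A sequence id found
    in both the strong and the weak file (or in both layer-1 files) is a
    label conflict.
    """
    non_enh = read_fasta(non_enhancer_source, policy)

    strong = read_fasta(strong_source, policy) if strong_source else []
    weak = read_fasta(weak_source, policy) if weak_source else []
    _check_unique_ids({"strong": strong, "weak": weak})
    strength = {s.id: STRONG for s in strong}
    strength.update({s.id: WEAK for s in weak})

    if enhancer_source is not None:
        enh = read_fasta(enhancer_source, policy)
        unmatched = set(strength) - {s.id for s in enh}
        if unmatched:
            raise LabelConflictError(
                "strong/weak ids absent from the enhancer source: "
                + ", ".join(sorted(unmatched)[:5])
            )
    else:
        if not strong and not weak:
            raise ValueError(
                "need an enhancer source or strong/weak sources to define "
                "the enhancer class"
            )
        enh = strong + weak
    _check_unique_ids({"enhancer": enh, "non_enhancer": non_enh})

    sequences = enh + non_enh
    layer1 = [ENHANCER] * len(enh) + [NON_ENHANCER] * len(non_enh)
    layer2: list[Optional[str]] = [
        strength.get(s.id, UNKNOWN) for s in enh
    ] + [None] * len(non_enh)

    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        logger.warning(
            "heterogeneous sequence lengths: %s", sorted(lengths)[:10]
        )
    ds = LabeledDataset(sequences, layer1, layer2)
    logger.info("loaded dataset with class counts %s", ds.class_counts())
    return ds


def read_label_map(path: str | Path) -> dict[str, str]:
    """Parse a two-column TSV label map (id <TAB> label)."""
    mapping: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sid, label = parts
            if sid in mapping and mapping[sid] != label:
                raise LabelConflictError(f"conflicting labels for id {sid!r}")
            mapping[sid] = label
    return mapping


def load_labeled_fasta(
    fasta: str | Path,
    label_map: str | Path,
    policy: Literal["strict", "skip_invalid"] = "strict",
) -> LabeledDataset:
    """Single-file loading: labels from a TSV map.

    Accepted labels per id: ``enhancer``, ``non_enhancer``, ``strong``,
    ``weak`` (the latter two imply enhancer).
    """
    seqs = read_fasta(fasta, policy)
    mapping = read_label_map(label_map)
    missing = [s.id for s in seqs if s.id not in mapping]
    if missing:
        raise ValueError(f"no label for id(s): {', '.join(missing[:5])}")
    layer1, layer2 = [], []
    for s in seqs:
        label = mapping[s.id]
        if label == NON_ENHANCER:
            layer1.append(NON_ENHANCER)
            layer2.append(None)
        elif label in (ENHANCER, STRONG, WEAK):
            layer1.append(ENHANCER)
            layer2.append(label if label in (STRONG, WEAK) else UNKNOWN)
        else:
            raise ValueError(f"unknown label {label!r} for id {s.id!r}")
    return LabeledDataset(seqs, layer1, layer2)


def write_dataset(dataset: LabeledDataset, outdir: str | Path) -> dict[str, Path]:
    """Write one FASTA per class group, mirroring ``load_dataset``'s layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups: dict[str, list[NucleotideSequence]] = {
        "non_enhancers": [],
        "strong_enhancers": [],
        "weak_enhancers": [],
        "enhancers_unknown_strength": [],
    }
    for seq, l1, l2 in zip(dataset.sequences, dataset.layer1, dataset.layer2):
        if l1 == NON_ENHANCER:
            groups["non_enhancers"].append(seq)
        elif l2 == STRONG:
            groups["strong_enhancers"].append(seq)
        elif l2 == WEAK:
            groups["weak_enhancers"].append(seq)
        else:
            groups["enhancers_unknown_strength"].append(seq)
    written: dict[str, Path] = {}
    for name, seqs in groups.items():
        if seqs:
            path = outdir / f"{name}.fasta"
            write_fasta(seqs, path)
            written[name] = path
    return written
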
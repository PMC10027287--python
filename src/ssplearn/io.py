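"""Peptide dataset I/O: FASTA sequences, 3-state structure strings, labels,
and reproducible stratified splits.

Sequences use the 20-letter amino-acid alphabet; anything else is an error,
never silently masked, because the model vocabulary (and the 20-substitution
mutagenesis grid) is exactly those residues.  Labels may ride in FASTA headers
as a ``|label=0/1`` suffix or in a sidecar TSV (``id<TAB>label``).  Secondary
structures are FASTA-style strings over {H, E, C} keyed by record id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
STRUCT_ALPHABET = "HEC"
DEFAULT_MAX_LEN = 250
_AA_SET = set(AA_ALPHABET)
_STRUCT_SET = set(STRUCT_ALPHABET)


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide: id, sequence, optional H/E/C structure, optional 0/1 label."""

    id: str
    sequence: str
    structure: str | None = None
    label: int | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue {sorted(bad)[0]!r} "
                f"(alphabet is {AA_ALPHABET})")
        if self.structure is not None:
            object.__setattr__(self, "structure", self.structure.upper())
            bad = set(self.structure) - _STRUCT_SET
            if bad:
                raise ValueError(
                    f"record {self.id!r}: illegal structure state {sorted(bad)[0]!r} "
                    "(3-state alphabet is H/E/C)")
            if len(self.structure) != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: structure length {len(self.structure)} "
                    f"!= sequence length {len(self.sequence)}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideDataset:
    """Ordered collection of records with unique ids."""

    records: list[PeptideRecord]
    name: str = "dataset"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate record id {dup!r} in dataset {self.name!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    def by_id(self, rid: str) -> PeptideRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def class_counts(self) -> tuple[int, int]:
        """(n_pos, n_neg) over labeled records."""
        n_pos = sum(1 for r in self.records if r.label == 1)
        n_neg = sum(1 for r in self.records if r.label == 0)
        return n_pos, n_neg

    def labels(self) -> np.ndarray:
        if any(r.label is None for r in self.records):
            raise ValueError("dataset contains unlabeled records")
        return np.array([r.label for r in self.records], dtype=int)


def _parse_header(header: str) -> tuple[str, int | None]:
    label = None
    rid = header
    if "|label=" in header:
        rid, _, tag = header.rpartition("|label=")
        tag = tag.strip()
        if tag not in ("0", "1"):
            raise ValueError(f"header {header!r}: label must be 0 or 1, got {tag!r}")
        label = int(tag)
    return rid.strip(), label


def read_fasta(path, max_len: int = DEFAULT_MAX_LEN, name: str | None = None) -> PeptideDataset:
    """Read peptides from FASTA.  Labels are parsed from a ``|label=`` header
    suffix when present.  Sequences longer than ``max_len`` are rejected."""
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        rid, label = _parse_header(entry.id if "|" in entry.id else entry.description.split()[0])
        seq = str(entry.seq)
        if len(seq) > max_len:
            raise ValueError(
                f"record {rid!r}: length {len(seq)} exceeds the maximum accepted "
                f"length {max_len}")
        records.append(PeptideRecord(id=rid, sequence=seq, label=label))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return PeptideDataset(records, name=name or str(path))


def write_fasta(dataset: PeptideDataset, path) -> None:
    """Write sequences, encoding labels as ``|label=`` header suffixes."""
    entries = []
    for r in dataset:
        rid = r.id if r.label is None else f"{r.id}|label={r.label}"
        entries.append(SeqRecord(Seq(r.sequence), id=rid, description=""))
    SeqIO.write(entries, str(path), "fasta")


def read_structures(path, dataset: PeptideDataset) -> PeptideDataset:
    """Attach H/E/C structure strings (FASTA-style, ids matching the dataset).

    Every record must be matched; lengths are validated against sequences.
    """
    structs: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        rid, _ = _parse_header(entry.id)
        structs[rid] = str(entry.seq)
    missing = [r.id for r in dataset if r.id not in structs]
    if missing:
        raise ValueError(f"structure file is missing ids: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    new_records = [replace(r, structure=structs[r.id]) for r in dataset]
    return PeptideDataset(new_records, name=dataset.name, metadata=dict(dataset.metadata))


def write_structures(dataset: PeptideDataset, path) -> None:
    entries = [SeqRecord(Seq(r.structure), id=r.id, description="")
               for r in dataset if r.structure is not None]
    SeqIO.write(entries, str(path), "fasta")


def read_labels_tsv(path, dataset: PeptideDataset) -> PeptideDataset:
    """Attach labels from a sidecar TSV (``id<TAB>label`` per line)."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(f"{path}:{ln}: expected 'id<TAB>0/1', got {line!r}")
            labels[parts[0]] = int(parts[1])
    missing = [r.id for r in dataset if r.id not in labels]
    if missing:
        raise ValueError(f"label file is missing ids: {missing[:10]}")
    new_records = [replace(r, label=labels[r.id]) for r in dataset]
    return PeptideDataset(new_records, name=dataset.name, metadata=dict(dataset.metadata))


def write_labels_tsv(dataset: PeptideDataset, path) -> None:
    with open(path, "w") as fh:
        for r in dataset:
            if r.label is not None:
                fh.write(f"{r.id}\t{r.label}\n")


def split_dataset(dataset: PeptideDataset, train_fraction: float,
                  seed: int) -> tuple[PeptideDataset, PeptideDataset]:
    """Deterministic label-stratified split into train/test partitions."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if any(r.label is None for r in dataset):
        unlabeled = [r.id for r in dataset if r.label is None]
        raise ValueError(f"cannot split: unlabeled records {unlabeled[:5]}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        idx = [i for i, r in enumerate(dataset) if r.label == cls]
        perm = rng.permutation(len(idx))
        n_train = int(round(train_fraction * len(idx)))
        for j, p in enumerate(perm):
            (train_idx if j < n_train else test_idx).append(idx[p])
    train_idx.sort()
    test_idx.sort()
    meta = dict(dataset.metadata)
    train = PeptideDataset([dataset[i] for i in train_idx],
                           name=f"{dataset.name}/train", metadata=meta)
    test = PeptideDataset([dataset[i] for i in test_idx],
                          name=f"{dataset.name}/test", metadata=meta)
    return train, test
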
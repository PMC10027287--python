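"""Handcrafted peptide feature encodings: AAC, CTDC, CTDT, CTDD, CTriad.

These are the classical fixed-length descriptors used as baselines against the
learned representation: amino-acid composition (20), the
composition/transition/distribution descriptors over 13 physicochemical
properties with 3 groups each (39/39/195), and the conjoint-triad counts over
7 residue classes (343).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ctd_tables import CTD_GROUPS, CTD_PROPERTIES, CTRIAD_CLASSES

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
SCHEME_DIMS = {"AAC": 20, "CTDC": 39, "CTDT": 39, "CTDD": 195, "CTriad": 343}

_AA_SET = set(AA_ALPHABET)

# residue -> group index (0/1/2) per property
_GROUP_OF = {
    prop: {aa: g for g, members in enumerate(CTD_GROUPS[prop]) for aa in members}
    for prop in CTD_PROPERTIES
}
# residue -> conjoint class index (0..6)
_CLASS_OF = {aa: c for c, members in enumerate(CTRIAD_CLASSES) for aa in members}


@dataclass(frozen=True)
class FeatureVector:
    scheme: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        if self.scheme not in SCHEME_DIMS:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if len(self.values) != SCHEME_DIMS[self.scheme]:
            raise ValueError(
                f"{self.scheme} vector must have length {SCHEME_DIMS[self.scheme]}, "
                f"got {len(self.values)}")


def _check_sequence(sequence: str, min_len: int = 1) -> str:
    sequence = sequence.upper()
    if len(sequence) < min_len:
        raise ValueError(f"sequence must have length >= {min_len}")
    bad = set(sequence) - _AA_SET
    if bad:
        raise ValueError(f"illegal residue {sorted(bad)[0]!r}")
    return sequence


def encode_aac(sequence: str) -> FeatureVector:
    """Amino-acid composition: count(a)/L per residue; sums to 1."""
    sequence = _check_sequence(sequence)
    L = len(sequence)
    values = np.array([sequence.count(a) for a in AA_ALPHABET], dtype=float) / L
    return FeatureVector("AAC", tuple(f"AAC.{a}" for a in AA_ALPHABET), values)


def encode_ctd(sequence: str, variant: str) -> FeatureVector:
    """CTD descriptors over 13 properties x 3 groups.

    C: group fractions (39).  T: adjacent-pair transition frequencies between
    distinct groups, normalized by L-1 (39).  D: for each group, the positions
    (as % of L, 1-based) of its 1st, 25%, 50%, 75% and 100% occurrence (195);
    groups absent from the sequence yield five zeros.
    """
    variant = variant.upper()
    if variant not in ("C", "T", "D"):
        raise ValueError("variant must be one of C, T, D")
    sequence = _check_sequence(sequence, min_len=2 if variant == "T" else 1)
    L = len(sequence)
    names: list[str] = []
    values: list[float] = []
    for prop in CTD_PROPERTIES:
        gmap = _GROUP_OF[prop]
        groups = [gmap[a] for a in sequence]
        if variant == "C":
            for g in range(3):
                names.append(f"CTDC.{prop}.G{g + 1}")
                values.append(groups.count(g) / L)
        elif variant == "T":
            pairs = list(zip(groups[:-1], groups[1:]))
            for (g1, g2) in ((0, 1), (0, 2), (1, 2)):
                names.append(f"CTDT.{prop}.T{g1 + 1}{g2 + 1}")
                n = sum(1 for p in pairs if p == (g1, g2) or p == (g2, g1))
                values.append(n / (L - 1))
        else:
            for g in range(3):
                positions = [i + 1 for i, gg in enumerate(groups) if gg == g]
                n = len(positions)
                cutoffs = [1, int(np.floor(0.25 * n)), int(np.floor(0.5 * n)),
                           int(np.floor(0.75 * n)), n]
                cutoffs = [max(c, 1) for c in cutoffs]
                for q, cut in zip((0, 25, 50, 75, 100), cutoffs):
                    names.append(f"CTDD.{prop}.G{g + 1}.P{q}")
                    values.append(positions[cut - 1] / L * 100 if n else 0.0)
    return FeatureVector(f"CTD{variant}", tuple(names), np.array(values))


def encode_ctriad(sequence: str) -> FeatureVector:
    """Conjoint triad: counts of all 343 class-triples over length-3 windows,
    normalized by the maximum count."""
    sequence = _check_sequence(sequence, min_len=3)
    classes = [_CLASS_OF[a] for a in sequence]
    counts = np.zeros((7, 7, 7))
    for i in range(len(classes) - 2):
        counts[classes[i], classes[i + 1], classes[i + 2]] += 1
    flat = counts.reshape(-1)
    mx = flat.max()
    values = flat / mx  # mx >= 1 for any L >= 3
    names = tuple(f"CTriad.g{a + 1}.g{b + 1}.g{c + 1}"
                  for a in range(7) for b in range(7) for c in range(7))
    return FeatureVector("CTriad", names, values)


_ENCODERS = {
    "AAC": encode_aac,
    "CTDC": lambda s: encode_ctd(s, "C"),
    "CTDT": lambda s: encode_ctd(s, "T"),
    "CTDD": lambda s: encode_ctd(s, "D"),
    "CTriad": encode_ctriad,
}


def encode(sequence: str, scheme: str) -> FeatureVector:
    if scheme not in _ENCODERS:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(_ENCODERS)}")
    return _ENCODERS[scheme](sequence)


def encode_dataset(dataset, scheme: str) -> pd.DataFrame:
    """Feature matrix for a dataset: one row per peptide, indexed by id."""
    rows = [encode(r.sequence, scheme) for r in dataset]
    return pd.DataFrame([fv.values for fv in rows],
                        index=[r.id for r in dataset],
                        columns=list(rows[0].names))
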
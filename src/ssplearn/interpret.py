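"""In-silico-mutagenesis interpretability for the hybrid-view classifier.

Every position of a peptide is substituted by each of the 19 alternative
residues and rescored (the structure view is held fixed at the wild-type
structure: mutant structures would require an external predictor, so this is
a documented approximation).  The resulting L x 20 delta grid drives
per-amino-acid contribution tables, |delta|-based positional importance
profiles, fixed-bin position-ratio maps for variable-length peptides,
head/tail clipping experiments, importance-guided motif extraction with MEME
minimal export, and 2-D latent-space projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .io import AA_ALPHABET, PeptideDataset, PeptideRecord
from .metrics import MetricReport, evaluate

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass
class IsmMatrix:
    """L x 20 grid of score deltas for every single-residue substitution.

    ``deltas[p, a]`` = score(sequence with position p set to residue a)
    - score(reference); the wild-type entries are exactly zero.
    """

    record_id: str
    reference_sequence: str
    deltas: np.ndarray
    wild_type_score: float

    def __post_init__(self):
        L = len(self.reference_sequence)
        if self.deltas.shape != (L, 20):
            raise ValueError(f"deltas must be {L} x 20, got {self.deltas.shape}")


def ism_scan(record: PeptideRecord, model, batch_size: int = 256) -> IsmMatrix:
    """Exhaustive single-residue mutagenesis rescoring of one peptide.

    ``model`` needs a ``predict_scores(records)`` method; the structure view
    is held fixed at the wild type across all mutants.
    """
    if not getattr(model, "trained", True):
        warnings.warn(f"ISM scan of {record.id!r} with an untrained model; "
                      "deltas reflect random initialization", stacklevel=2)
    seq = record.sequence
    L = len(seq)
    variants: list[str] = []
    slots: list[tuple[int, int]] = []
    for p in range(L):
        for a in AA_ALPHABET:
            if a == seq[p]:
                continue
            variants.append(seq[:p] + a + seq[p + 1:])
            slots.append((p, _AA_INDEX[a]))
    if hasattr(model, "score_sequence_variants"):
        wt_score = float(model.score_sequence_variants(record, [seq])[0])
        scores = model.score_sequence_variants(record, variants, batch_size=batch_size)
    else:  # any scorer exposing predict_scores(records) works
        wt_score = float(model.predict_scores([record])[0])
        mutants = [_dc_replace(record, id=f"{record.id}:{p}:{a}", sequence=s)
                   for s, (p, a) in zip(variants, slots)]
        scores = np.concatenate([model.predict_scores(mutants[i:i + batch_size])
                                 for i in range(0, len(mutants), batch_size)])
    deltas = np.zeros((L, 20))
    for (p, ai), s in zip(slots, scores):
        deltas[p, ai] = s - wt_score
    return IsmMatrix(record_id=record.id, reference_sequence=seq,
                     deltas=deltas, wild_type_score=wt_score)


def ism_to_frame(matrix: IsmMatrix) -> pd.DataFrame:
    """CSV-friendly view: rows = positions, columns = the 20 residues."""
    return pd.DataFrame(matrix.deltas,
                        index=pd.RangeIndex(len(matrix.reference_sequence), name="position"),
                        columns=list(AA_ALPHABET))


@dataclass
class ContributionTable:
    """Per-amino-acid accumulated substitution scores per class, with the
    class amino-acid composition (AAC) as the statistical reference."""

    contributions: pd.DataFrame  # index = residues, columns = class names
    aac: pd.DataFrame


def accumulate_contributions(matrices_by_class: dict[str, list[IsmMatrix]],
                             direction: str = "to") -> ContributionTable:
    """Sum ISM deltas into one score per amino acid and class.

    ``direction='to'`` (default, used in reports): for each target residue a,
    sum deltas of substituting *to* a over positions and peptides.
    ``direction='from'``: attribute each row's summed deltas to the reference
    residue being replaced.
    """
    if direction not in ("to", "from"):
        raise ValueError("direction must be 'to' or 'from'")
    contrib = {}
    aac = {}
    for cls, matrices in matrices_by_class.items():
        if not matrices:
            raise ValueError(f"class {cls!r} has no ISM matrices")
        total = np.zeros(20)
        counts = np.zeros(20)
        n_res = 0
        for m in matrices:
            if direction == "to":
                total += m.deltas.sum(axis=0)
            else:
                for p, ref in enumerate(m.reference_sequence):
                    total[_AA_INDEX[ref]] += m.deltas[p].sum()
            for a in m.reference_sequence:
                counts[_AA_INDEX[a]] += 1
            n_res += len(m.reference_sequence)
        contrib[cls] = total
        aac[cls] = counts / n_res
    idx = pd.Index(list(AA_ALPHABET), name="residue")
    return ContributionTable(contributions=pd.DataFrame(contrib, index=idx),
                             aac=pd.DataFrame(aac, index=idx))


def importance_profile(matrix: IsmMatrix) -> np.ndarray:
    """Per-position importance: mean |delta| over the 19 substitutions."""
    return np.abs(matrix.deltas).sum(axis=1) / 19.0


def bin_by_position_ratio(values, n_bins: int) -> np.ndarray:
    """Aggregate per-position values onto a fixed position-ratio axis.

    Bin b collects positions p with floor(p / L * n_bins) = b (clipped to the
    last bin); the aggregate is the within-peptide sum.  Bins with no position
    (possible when L < n_bins) are NaN, not zero.
    """
    values = np.asarray(values, dtype=float)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    L = len(values)
    if L == 0:
        raise ValueError("empty profile")
    # floor(p / L * n_bins) in exact integer arithmetic
    idx = np.minimum(np.arange(L) * n_bins // L, n_bins - 1)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            out[b] = values[mask].sum()
    return out


def pooled_binned_importance(matrices: list[IsmMatrix], n_bins: int) -> np.ndarray:
    """[n_peptides, n_bins] matrix of binned importance profiles (NaN-padded)."""
    return np.vstack([bin_by_position_ratio(importance_profile(m), n_bins)
                      for m in matrices])


def residue_position_map(matrices: list[IsmMatrix], n_bins: int = 50,
                         normalize: bool = False) -> pd.DataFrame:
    """Residue x position-ratio importance map (20 x n_bins): summed |delta|
    of substitutions to each residue per bin; with ``normalize=True`` each
    cell is divided by its bin occupancy."""
    total = np.zeros((20, n_bins))
    occupancy = np.zeros(n_bins)
    for m in matrices:
        L = len(m.reference_sequence)
        idx = np.minimum(np.arange(L) * n_bins // L, n_bins - 1)
        for p in range(L):
            total[:, idx[p]] += np.abs(m.deltas[p])
            occupancy[idx[p]] += 1
    if normalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            total = total / occupancy[None, :]
    return pd.DataFrame(total, index=list(AA_ALPHABET),
                        columns=[f"bin{b}" for b in range(n_bins)])


@dataclass
class ClippingCurve:
    direction: str
    ratios: list[float]
    reports: list[MetricReport]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"direction": self.direction, "ratio": r, **rep.to_dict()}
                for r, rep in zip(self.ratios, self.reports)]
        return pd.DataFrame(rows)


def clip_record(record: PeptideRecord, ratio: float, direction: str) -> PeptideRecord:
    """Forward clipping removes the first floor(ratio*L) residues (conserving
    the tail); backward removes the last floor(ratio*L) (conserving the head).
    The structure string is clipped identically."""
    if not 0 <= ratio < 1:
        raise ValueError("clip ratio must be in [0, 1)")
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    L = len(record.sequence)
    n = int(np.floor(ratio * L))
    if direction == "forward":
        seq = record.sequence[n:]
        struct = record.structure[n:] if record.structure is not None else None
    else:
        seq = record.sequence[: L - n] if n else record.sequence
        struct = (record.structure[: L - n] if n else record.structure) \
            if record.structure is not None else None
    return _dc_replace(record, sequence=seq, structure=struct)


DEFAULT_CLIP_RATIOS = [round(0.1 * i, 1) for i in range(10)]  # 0.0 .. 0.9


def clipping_experiment(dataset: PeptideDataset, model, ratios=None,
                        direction: str = "forward") -> ClippingCurve:
    """Re-evaluate the model on head- or tail-truncated copies of the dataset."""
    ratios = DEFAULT_CLIP_RATIOS if ratios is None else list(ratios)
    labels = dataset.labels()
    reports = []
    for r in ratios:
        clipped = [clip_record(rec, r, direction) for rec in dataset]
        _, preds = model.predict(clipped)
        reports.append(evaluate(labels, preds))
    return ClippingCurve(direction=direction, ratios=ratios, reports=reports)


@dataclass
class MotifModel:
    """Importance-selected motif: the chosen bin window on the position-ratio
    axis, per-record residue windows, and a column-stochastic PWM."""

    window_bins: tuple[int, int]  # [start, end) on the position-ratio axis
    n_bins: int
    pwm: pd.DataFrame  # positions x 20 residues, rows sum to 1
    source_count: int
    windows: dict[str, tuple[int, int]]  # record id -> [start, end) residues


def extract_motif(profiles: np.ndarray, dataset: PeptideDataset,
                  window_bins: int, n_bins: int | None = None,
                  pseudocount: float = 0.01) -> MotifModel:
    """Select the contiguous ``window_bins``-wide bin window maximizing pooled
    importance, map it back to residue coordinates per peptide, and build a
    PWM from the extracted subsequences."""
    profiles = np.asarray(profiles, dtype=float)
    n_bins = profiles.shape[1] if n_bins is None else n_bins
    if window_bins < 1 or window_bins > n_bins:
        raise ValueError(f"window_bins must be in [1, {n_bins}]")
    if profiles.shape[0] != len(dataset):
        raise ValueError("profiles and dataset must align row-by-record")
    pooled = np.nanmean(profiles, axis=0)
    pooled = np.nan_to_num(pooled, nan=0.0)
    sums = np.array([pooled[s:s + window_bins].sum()
                     for s in range(n_bins - window_bins + 1)])
    start_bin = int(np.argmax(sums))
    end_bin = start_bin + window_bins
    windows: dict[str, tuple[int, int]] = {}
    subseqs: list[str] = []
    for rec in dataset:
        L = len(rec.sequence)
        s = int(np.floor(start_bin / n_bins * L))
        e = max(s + 1, int(np.ceil(end_bin / n_bins * L)))
        windows[rec.id] = (s, min(e, L))
        subseqs.append(rec.sequence[s:min(e, L)])
    width = min(len(s) for s in subseqs)
    counts = np.full((width, 20), pseudocount)
    for s in subseqs:
        for j in range(width):
            counts[j, _AA_INDEX[s[j]]] += 1
    pwm = counts / counts.sum(axis=1, keepdims=True)
    return MotifModel(window_bins=(start_bin, end_bin), n_bins=n_bins,
                      pwm=pd.DataFrame(pwm, columns=list(AA_ALPHABET)),
                      source_count=len(subseqs), windows=windows)


def write_meme(motif: MotifModel, path, name: str = "motif1") -> None:
    """MEME minimal-format export for downstream motif-comparison tools."""
    pwm = motif.pwm.values
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AA_ALPHABET + "\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{a} 0.05000" for a in AA_ALPHABET) + "\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 20 w= {pwm.shape[0]} "
                 f"nsites= {motif.source_count} E= 0\n")
        for row in pwm:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def project_latent(representations: np.ndarray, labels, method: str = "PCA",
                   seed: int = 0) -> pd.DataFrame:
    """2-D projection of representation vectors (PCA deterministic up to sign;
    t-SNE seeded), with labels preserved for plotting."""
    X = np.asarray(representations, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points to project")
    if X.shape[1] < 2:
        raise ValueError("representation dimension must be >= 2")
    method = method.upper()
    if method == "PCA":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed).fit_transform(X)
    elif method in ("TSNE", "T-SNE"):
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (X.shape[0] - 1) / 3.0)
        coords = TSNE(n_components=2, random_state=seed, init="pca",
                      perplexity=perplexity).fit_transform(X)
    else:
        raise ValueError("method must be 'PCA' or 'tSNE'")
    return pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "label": labels})
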
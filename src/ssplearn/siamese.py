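"""Siamese contrastive training of the hybrid-view model.

Training alternates two phases per epoch.  In the Siamese phase, record pairs
are pushed through both view towers; the contrastive loss
``L1 = 1/2 (1-Y) D^2 + 1/2 Y max(0, m-D)^2`` (Y=0 for same-label pairs, Y=1
otherwise, D the Euclidean representation distance) shapes the towers, while
per-view discriminators receive gradient-detached representations so their
cross-entropy terms update discriminator parameters only (the freezing
contract).  In the fusion phase the towers are frozen and a discriminator over
the concatenated sequence+structure representations is fit by cross-entropy;
inference always uses this fused discriminator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .io import PeptideDataset, PeptideRecord
from .metrics import MetricReport, evaluate
from .nn import (Discriminator, EncoderTower, ModelConfig, encode_sequence_tokens,
                 encode_structure_tokens, load_params, save_params)

EPS = 1e-7  # cross-entropy probability clamp


@dataclass(frozen=True)
class PeptidePair:
    """Two labeled records with the pair indicator Y (0 same label, 1 different)."""

    a: PeptideRecord
    b: PeptideRecord
    Y: int

    def __post_init__(self):
        if self.a.label is None or self.b.label is None:
            raise ValueError("paired records must be labeled")
        expected = 0 if self.a.label == self.b.label else 1
        if self.Y != expected:
            raise ValueError(f"pair indicator Y={self.Y} inconsistent with labels "
                             f"({self.a.label}, {self.b.label})")


@dataclass
class LossBreakdown:
    contrastive_seq: float
    contrastive_struct: float
    ce_a: float
    ce_b: float

    @property
    def total(self) -> float:
        return self.contrastive_seq + self.contrastive_struct + self.ce_a + self.ce_b


# -- loss primitives ---------------------------------------------------------
def euclidean_distance(v1, v2):
    """D = ||v1 - v2||_2; works on NumPy vectors (float) or Tensors (Tensor)."""
    if isinstance(v1, Tensor) or isinstance(v2, Tensor):
        d = ad.as_tensor(v1) - ad.as_tensor(v2)
        return ad.sqrt((d * d).sum(axis=-1) + 1e-12)
    v1, v2 = np.asarray(v1, float), np.asarray(v2, float)
    if v1.shape != v2.shape:
        raise ValueError(f"length mismatch: {v1.shape} vs {v2.shape}")
    return float(np.linalg.norm(v1 - v2))


def contrastive_loss(v1, v2, Y, m: float):
    """L1 = 1/2 (1-Y) D^2 + 1/2 Y max(0, m - D)^2, with margin m > 0."""
    if not m > 0:
        raise ValueError("margin m must be > 0")
    if isinstance(v1, Tensor) or isinstance(v2, Tensor):
        d = ad.as_tensor(v1) - ad.as_tensor(v2)
        d2 = (d * d).sum(axis=-1)
        dist = ad.sqrt(d2 + 1e-12)
        hinge = ad.relu(m - dist)
        y = ad.as_tensor(Y)
        return 0.5 * (1.0 - y) * d2 + 0.5 * y * hinge * hinge
    dist = euclidean_distance(v1, v2)
    return float(0.5 * (1 - Y) * dist ** 2 + 0.5 * Y * max(0.0, m - dist) ** 2)


def cross_entropy(score, label):
    """-Y log s - (1-Y) log(1-s), with s clamped to [eps, 1-eps]."""
    if isinstance(score, Tensor):
        s = ad.clip(score, EPS, 1.0 - EPS)
        y = ad.as_tensor(label)
        return -(y * ad.log(s) + (1.0 - y) * ad.log(1.0 - s))
    s = min(max(float(score), EPS), 1.0 - EPS)
    return float(-(label * np.log(s) + (1 - label) * np.log(1.0 - s)))


def fuse_views(v_seq, v_struct):
    """Concatenate the two view representations (length 2 * proj_dim)."""
    if isinstance(v_seq, Tensor) or isinstance(v_struct, Tensor):
        return ad.concat([ad.as_tensor(v_seq), ad.as_tensor(v_struct)], axis=-1)
    v_seq, v_struct = np.asarray(v_seq, float), np.asarray(v_struct, float)
    if v_seq.ndim != v_struct.ndim:
        raise ValueError("views must have matching rank")
    return np.concatenate([v_seq, v_struct], axis=-1)


# -- model -------------------------------------------------------------------
class HybridSiameseModel:
    """Two parameter-disjoint encoder towers (sequence, structure), two
    training-time per-view discriminators, and the fused-view discriminator
    used for inference."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.tower_seq = EncoderTower(vocab_size=21, config=config, rng=rng)
        self.tower_struct = EncoderTower(vocab_size=4, config=config, rng=rng)
        self.disc_seq = Discriminator(rng, config.proj_dim)
        self.disc_struct = Discriminator(rng, config.proj_dim)
        self.disc_fused = Discriminator(rng, 2 * config.proj_dim)
        self.trained = False

    def _modules(self) -> dict:
        return {"tower_seq": self.tower_seq, "tower_struct": self.tower_struct,
                "disc_seq": self.disc_seq, "disc_struct": self.disc_struct,
                "disc_fused": self.disc_fused}

    def tower_parameters(self):
        return self.tower_seq.parameters() + self.tower_struct.parameters()

    # -- batching ------------------------------------------------------------
    @staticmethod
    def _pad_tokens(token_lists: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        lengths = np.array([len(t) for t in token_lists])
        L = int(lengths.max())
        out = np.zeros((len(token_lists), L), dtype=np.int64)
        for i, t in enumerate(token_lists):
            out[i, : len(t)] = t
        return out, lengths

    def _encode_records(self, records: list[PeptideRecord], view: str,
                        train: bool = False) -> Tensor:
        if view == "seq":
            toks = [encode_sequence_tokens(r.sequence) for r in records]
            tower = self.tower_seq
        else:
            for r in records:
                if r.structure is None:
                    raise ValueError(f"record {r.id!r} has no structure; the hybrid "
                                     "model requires both views")
            toks = [encode_structure_tokens(r.structure) for r in records]
            tower = self.tower_struct
        padded, lengths = self._pad_tokens(toks)
        return tower.forward_batch(padded, lengths, train=train)

    def representations(self, records: list[PeptideRecord] | PeptideDataset,
                        batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
        """Evaluation-mode (v_seq, v_struct) arrays for a set of records."""
        records = list(records)
        vs, vt = [], []
        with ad.no_grad():
            for i in range(0, len(records), batch_size):
                chunk = records[i:i + batch_size]
                vs.append(self._encode_records(chunk, "seq").data)
                vt.append(self._encode_records(chunk, "struct").data)
        return np.vstack(vs), np.vstack(vt)

    def predict_scores(self, records, batch_size: int = 64) -> np.ndarray:
        """Fused-view scores in [0, 1] per record."""
        v_seq, v_struct = self.representations(records, batch_size)
        with ad.no_grad():
            fused = Tensor(fuse_views(v_seq, v_struct))
            return self.disc_fused(fused).data

    def predict(self, records) -> tuple[np.ndarray, np.ndarray]:
        """(scores, labels); label 1 iff score strictly above 0.5."""
        scores = self.predict_scores(records)
        return scores, (scores > 0.5).astype(int)

    def score_sequence_variants(self, record: PeptideRecord, sequences: list[str],
                                batch_size: int = 256) -> np.ndarray:
        """Scores for same-length sequence variants of one record, holding the
        structure view fixed at the record's own structure.  Encoding the
        structure once makes exhaustive mutagenesis scans ~2x cheaper."""
        if record.structure is None:
            raise ValueError(f"record {record.id!r} has no structure")
        with ad.no_grad():
            v_struct = self._encode_records([record], "struct").data  # [1, P]
            scores = np.empty(len(sequences))
            for i in range(0, len(sequences), batch_size):
                chunk = sequences[i:i + batch_size]
                toks = [encode_sequence_tokens(s) for s in chunk]
                padded, lengths = self._pad_tokens(toks)
                v_seq = self.tower_seq.forward_batch(padded, lengths).data
                fused = np.concatenate(
                    [v_seq, np.repeat(v_struct, len(chunk), axis=0)], axis=-1)
                scores[i:i + len(chunk)] = self.disc_fused(Tensor(fused)).data
        return scores

    def reinitialize(self, seed: int) -> None:
        """Redraw every parameter from the init distribution under ``seed``
        (architecture and config unchanged)."""
        from dataclasses import replace as _dc_replace

        fresh = HybridSiameseModel(_dc_replace(self.config, seed=int(seed)))
        mine = [p for mod in self._modules().values() for p in mod.parameters()]
        theirs = [p for mod in fresh._modules().values() for p in mod.parameters()]
        for p, q in zip(mine, theirs):
            p.data[...] = q.data

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        save_params(self._modules(), self.config, path)

    @classmethod
    def load(cls, path) -> "HybridSiameseModel":
        import json

        with np.load(path) as npz:
            config = ModelConfig.from_dict(json.loads(bytes(npz["__config__"]).decode()))
        model = cls(config)
        load_params(model._modules(), path)
        model.trained = True
        return model


# -- pair sampling -----------------------------------------------------------
def sample_pairs(dataset: PeptideDataset, n_pairs: int, seed: int) -> list[PeptidePair]:
    """Seeded uniform pair sampling with a 50/50 same/different-label target;
    no record is ever paired with itself."""
    records = list(dataset)
    labels = dataset.labels()
    pos = [r for r, y in zip(records, labels) if y == 1]
    neg = [r for r, y in zip(records, labels) if y == 0]
    if not pos or not neg:
        raise ValueError("pair sampling requires both classes (no Y=1 pairs exist "
                         "in a single-class dataset)")
    rng = np.random.default_rng(seed)
    pairs: list[PeptidePair] = []
    for _ in range(n_pairs):
        if rng.random() < 0.5:  # same-label pair (Y=0)
            pool = pos if (rng.random() < 0.5 and len(pos) >= 2) or len(neg) < 2 else neg
            i, j = rng.choice(len(pool), size=2, replace=False)
            pairs.append(PeptidePair(pool[i], pool[j], Y=0))
        else:  # different-label pair (Y=1)
            pairs.append(PeptidePair(pos[rng.integers(len(pos))],
                                     neg[rng.integers(len(neg))], Y=1))
    return pairs


# -- losses over batches -----------------------------------------------------
def _pair_batch_losses(model: HybridSiameseModel, pairs: list[PeptidePair],
                       train: bool = False) -> dict[str, Tensor]:
    """Per-view contrastive and per-record cross-entropy terms for a pair batch.

    Representations fed to the per-view discriminators are detached, so the
    cross-entropy terms carry no gradient into the towers.
    """
    a = [p.a for p in pairs]
    b = [p.b for p in pairs]
    Y = np.array([p.Y for p in pairs], dtype=float)
    Ya = np.array([p.a.label for p in pairs], dtype=float)
    Yb = np.array([p.b.label for p in pairs], dtype=float)
    m = model.config.margin
    out: dict[str, Tensor] = {}
    ce_a_terms, ce_b_terms = [], []
    for view, disc in (("seq", model.disc_seq), ("struct", model.disc_struct)):
        va = model._encode_records(a, view, train=train)
        vb = model._encode_records(b, view, train=train)
        out[f"contrastive_{view}"] = contrastive_loss(va, vb, Tensor(Y), m)
        ce_a_terms.append(cross_entropy(disc(va.detach()), Tensor(Ya)))
        ce_b_terms.append(cross_entropy(disc(vb.detach()), Tensor(Yb)))
    out["ce_a"] = ce_a_terms[0] + ce_a_terms[1]
    out["ce_b"] = ce_b_terms[0] + ce_b_terms[1]
    out["total"] = (out["contrastive_seq"] + out["contrastive_struct"]
                    + out["ce_a"] + out["ce_b"])
    return out


def combined_loss(pair: PeptidePair, model: HybridSiameseModel,
                  config: ModelConfig | None = None,
                  return_tensors: bool = False):
    """Comprehensive loss for one pair: L = L1(v1,v2,Y) + L2(v1,Y1) + L2(v2,Y2)
    per view, both views summed.  With ``return_tensors=True`` the live graph
    tensors are returned (for gradient inspection)."""
    for r in (pair.a, pair.b):
        if r.structure is None:
            raise ValueError(f"record {r.id!r} lacks a structure string")
        if r.label is None:
            raise ValueError(f"record {r.id!r} lacks a label")
    terms = _pair_batch_losses(model, [pair], train=False)
    if return_tensors:
        return terms
    return LossBreakdown(
        contrastive_seq=float(terms["contrastive_seq"].data[0]),
        contrastive_struct=float(terms["contrastive_struct"].data[0]),
        ce_a=float(terms["ce_a"].data[0]),
        ce_b=float(terms["ce_b"].data[0]),
    )


# -- training ----------------------------------------------------------------
@dataclass
class TrainConfig:
    """Optimization knobs (the architecture lives in ModelConfig)."""

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 5e-3
    pairs_per_epoch: int | None = None  # default: one pair per training record
    fusion_passes: int = 2  # fused-head sweeps per epoch (towers frozen)
    final_fusion_passes: int = 3  # extra fused-head sweeps after the last epoch
    keep_best: bool = True  # restore the epoch with the best training accuracy
    n_restarts: int = 4  # candidate initializations tried before committing
    restart_epochs: int = 3  # probe epochs per candidate initialization
    log_every: int = 1


def _batched(items: list, batch_size: int):
    for i in range(0, len(items), batch_size):
        yield items[i:i + batch_size]


def _all_params(model: HybridSiameseModel) -> list:
    return [p for mod in model._modules().values() for p in mod.parameters()]


def _fit(model: HybridSiameseModel, train_set: PeptideDataset,
         train_cfg: TrainConfig, eval_set: PeptideDataset | None,
         seed: int, n_epochs: int, keep_best: bool,
         initial_best: tuple[float, list] | None = None,
         epoch_offset: int = 0) -> list[dict]:
    """Run ``n_epochs`` of the two-phase loop on ``model`` in place."""
    n_pairs = train_cfg.pairs_per_epoch or len(train_set)
    opt_siamese = Adam(model.tower_parameters() + model.disc_seq.parameters()
                       + model.disc_struct.parameters(), lr=train_cfg.learning_rate)
    opt_fusion = Adam(model.disc_fused.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(seed)
    records = list(train_set)
    labels = train_set.labels().astype(float)
    log: list[dict] = []
    all_params = _all_params(model)
    best_acc, best_state = initial_best if initial_best else (-1.0, None)
    for epoch in range(n_epochs):
        # phase (i): Siamese contrastive + detached per-view cross-entropy
        pairs = sample_pairs(train_set, n_pairs, seed=int(rng.integers(2 ** 31)))
        pairs.sort(key=lambda p: max(len(p.a), len(p.b)))  # length bucketing
        sums = {"contrastive_seq": 0.0, "contrastive_struct": 0.0,
                "ce_a": 0.0, "ce_b": 0.0}
        n_seen = 0
        for batch in _batched(pairs, train_cfg.batch_size):
            terms = _pair_batch_losses(model, batch, train=True)
            loss = terms["total"].mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss "
                    f"(components: { {k: float(np.sum(v.data)) for k, v in terms.items() if k != 'total'} })")
            opt_siamese.zero_grad()
            loss.backward()
            opt_siamese.step()
            for k in sums:
                sums[k] += float(terms[k].data.sum())
            n_seen += len(batch)
        # phase (ii): fused discriminator on frozen towers; representations are
        # cached once per epoch since the towers do not move inside this phase
        v_seq, v_struct = model.representations(records, batch_size=train_cfg.batch_size)
        fused_all = np.concatenate([v_seq, v_struct], axis=-1)
        n_passes = train_cfg.fusion_passes
        if epoch == n_epochs - 1:
            n_passes += train_cfg.final_fusion_passes
        fusion_ce = 0.0
        correct = 0
        for p in range(n_passes):
            order = rng.permutation(len(records))
            fusion_ce = 0.0
            correct = 0
            for idx_batch in _batched(list(order), train_cfg.batch_size):
                y = labels[list(idx_batch)]
                scores = model.disc_fused(Tensor(fused_all[list(idx_batch)]))
                loss = cross_entropy(scores, Tensor(y)).mean()
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"fusion phase diverged at epoch {epoch}")
                opt_fusion.zero_grad()
                loss.backward()
                opt_fusion.step()
                fusion_ce += float(cross_entropy(scores.detach(), Tensor(y)).data.sum())
                correct += int(((scores.data > 0.5).astype(int) == y.astype(int)).sum())
        entry = {
            "epoch": epoch + epoch_offset,
            "contrastive_seq": sums["contrastive_seq"] / n_seen,
            "contrastive_struct": sums["contrastive_struct"] / n_seen,
            "ce_a": sums["ce_a"] / n_seen,
            "ce_b": sums["ce_b"] / n_seen,
            "fusion_ce": fusion_ce / len(records),
            "train_acc": correct / len(records),
        }
        if keep_best and entry["train_acc"] >= best_acc:
            best_acc = entry["train_acc"]
            best_state = [p.data.copy() for p in all_params]
        if eval_set is not None and (epoch % train_cfg.log_every == 0
                                     or epoch == n_epochs - 1):
            _, preds = model.predict(eval_set)
            report = evaluate(eval_set.labels(), preds)
            entry.update({f"eval_{k}": v for k, v in report.to_dict().items()})
        log.append(entry)
    if keep_best and best_state is not None:
        for p, data in zip(all_params, best_state):
            p.data[...] = data
    return log


def train(model: HybridSiameseModel, train_set: PeptideDataset,
          train_cfg: TrainConfig | None = None,
          eval_set: PeptideDataset | None = None,
          seed: int | None = None) -> list[dict]:
    """Two-phase training with seeded multi-restart initialization.

    When ``n_restarts > 1`` and the epoch budget allows, each candidate
    initialization is probed for ``restart_epochs`` epochs and the one with
    the best training accuracy is trained for the remaining epochs (a standard
    remedy for the contrastive phase occasionally starting in a flat basin).
    Returns the per-epoch log; with ``keep_best`` the parameters of the best
    training-accuracy epoch are restored at the end.
    """
    train_cfg = train_cfg or TrainConfig()
    seed = model.config.seed if seed is None else seed
    for r in train_set:
        if r.label is None:
            raise ValueError(f"record {r.id!r} is unlabeled")
        if r.structure is None:
            raise ValueError(f"record {r.id!r} has no structure string")
    n_restarts = max(1, train_cfg.n_restarts)
    probe = min(train_cfg.restart_epochs, train_cfg.epochs)
    if n_restarts > 1 and 0 < probe < train_cfg.epochs:
        candidates = []
        for rix in range(n_restarts):
            init_seed = model.config.seed if rix == 0 else \
                int((model.config.seed + 7919 * rix) % (2 ** 31))
            model.reinitialize(init_seed)
            head = _fit(model, train_set, train_cfg, None, seed, probe,
                        keep_best=False)
            state = [p.data.copy() for p in _all_params(model)]
            candidates.append((head[-1]["train_acc"], -rix, state, head))
        acc, _, state, head = max(candidates, key=lambda c: (c[0], c[1]))
        for p, data in zip(_all_params(model), state):
            p.data[...] = data
        tail = _fit(model, train_set, train_cfg, eval_set,
                    int((seed + 1) % (2 ** 31)), train_cfg.epochs - probe,
                    keep_best=train_cfg.keep_best, initial_best=(acc, state),
                    epoch_offset=probe)
        log = head + tail
    else:
        log = _fit(model, train_set, train_cfg, eval_set, seed, train_cfg.epochs,
                   keep_best=train_cfg.keep_best)
    model.trained = True
    return log


def class_distance_summary(model: HybridSiameseModel,
                           dataset: PeptideDataset) -> dict[str, float]:
    """Mean intra-class vs inter-class representation distances per view —
    the geometry the contrastive objective is meant to induce."""
    v_seq, v_struct = model.representations(dataset)
    y = dataset.labels()
    out = {}
    for view, V in (("seq", v_seq), ("struct", v_struct)):
        d = np.sqrt(((V[:, None, :] - V[None, :, :]) ** 2).sum(-1))
        same = (y[:, None] == y[None, :]) & ~np.eye(len(y), dtype=bool)
        diff = y[:, None] != y[None, :]
        out[f"intra_{view}"] = float(d[same].mean())
        out[f"inter_{view}"] = float(d[diff].mean())
    return out
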
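"""Mutagenesis matrices, contributions, importance binning, clipping, motifs,
latent projections — checked against constructed scorers and flat-loop oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ssplearn.interpret import (ClippingCurve, IsmMatrix, accumulate_contributions,
                                bin_by_position_ratio, clip_record,
                                clipping_experiment, extract_motif,
                                importance_profile, ism_scan, ism_to_frame,
                                pooled_binned_importance, project_latent,
                                residue_position_map, write_meme)
from ssplearn.io import AA_ALPHABET, PeptideDataset, PeptideRecord
from ssplearn.metrics import evaluate

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


class PositionScorer:
    """Stub model whose score depends only on the residue at one position."""

    trained = True

    def __init__(self, position: int, favored: str, base: float = 0.4, boost: float = 0.5):
        self.position = position
        self.favored = favored
        self.base = base
        self.boost = boost

    def predict_scores(self, records):
        return np.array([self.base + (self.boost if r.sequence[self.position]
                                      in self.favored else 0.0) for r in records])


class CompositionScorer:
    """Stub model scoring by I/L/F fraction; classifies the synthetic classes."""

    trained = True

    def __init__(self, threshold: float = 0.18):
        self.threshold = threshold

    def predict_scores(self, records):
        frac = np.array([sum(r.sequence.count(a) for a in "ILF") / len(r.sequence)
                         for r in records])
        return 1.0 / (1.0 + np.exp(-40 * (frac - self.threshold)))

    def predict(self, records):
        s = self.predict_scores(records)
        return s, (s > 0.5).astype(int)


def _record(seq="MKLIFACDEF", rid="r0", label=1):
    return PeptideRecord(rid, seq, structure="C" * len(seq), label=label)


# -- ISM ---------------------------------------------------------------------
def test_ism_wild_type_entries_zero_and_shape():
    rec = _record()
    m = ism_scan(rec, PositionScorer(2, "L"))
    assert m.deltas.shape == (len(rec.sequence), 20)
    for p, a in enumerate(rec.sequence):
        assert m.deltas[p, _AA_INDEX[a]] == 0.0
    # each row: at most 19 nonzero entries
    assert (np.count_nonzero(m.deltas, axis=1) <= 19).all()


def test_ism_localizes_constructed_signal():
    """A scorer reading only position 2 yields zero rows everywhere else."""
    rec = _record("MKLIFACDEF")
    m = ism_scan(rec, PositionScorer(2, "L"))
    nonzero_rows = set(np.flatnonzero(np.abs(m.deltas).sum(axis=1)))
    assert nonzero_rows == {2}
    # mutating L (favored) away drops the score by `boost`
    assert m.deltas[2, _AA_INDEX["A"]] == pytest.approx(-0.5)


def test_ism_warns_on_untrained_model():
    scorer = PositionScorer(0, "M")
    scorer.trained = False
    with pytest.warns(UserWarning, match="untrained"):
        ism_scan(_record(), scorer)


def test_ism_frame_layout():
    m = ism_scan(_record("MKL"), PositionScorer(0, "M"))
    frame = ism_to_frame(m)
    assert frame.shape == (3, 20)
    assert list(frame.columns) == list(AA_ALPHABET)


# -- contributions -----------------------------------------------------------
def _random_matrix(rng, seq):
    deltas = rng.normal(size=(len(seq), 20))
    for p, a in enumerate(seq):
        deltas[p, _AA_INDEX[a]] = 0.0
    return IsmMatrix(record_id=f"m{rng.integers(1e6)}", reference_sequence=seq,
                     deltas=deltas, wild_type_score=0.5)


def test_contribution_zero_matrix():
    m = IsmMatrix("z", "MK", np.zeros((2, 20)), 0.5)
    table = accumulate_contributions({"SSP": [m]})
    assert np.all(table.contributions.values == 0.0)


def test_contribution_two_position_example():
    deltas = np.zeros((2, 20))
    deltas[0, _AA_INDEX["L"]] = 0.2
    deltas[1, _AA_INDEX["L"]] = 0.3
    m = IsmMatrix("x", "MK", deltas, 0.5)
    table = accumulate_contributions({"SSP": [m]})
    assert table.contributions.loc["L", "SSP"] == pytest.approx(0.5)


def test_contribution_matches_flat_double_loop(rng):
    seqs = ["".join(rng.choice(list(AA_ALPHABET), size=int(rng.integers(5, 15))))
            for _ in range(5)]
    mats = [_random_matrix(rng, s) for s in seqs]
    table = accumulate_contributions({"SSP": mats})
    expected = np.zeros(20)
    for m in mats:
        for p in range(len(m.reference_sequence)):
            for a in range(20):
                expected[a] += m.deltas[p, a]
    np.testing.assert_allclose(table.contributions["SSP"].values, expected)
    # AAC reference really is the pooled composition
    counts = np.zeros(20)
    for s in seqs:
        for a in s:
            counts[_AA_INDEX[a]] += 1
    np.testing.assert_allclose(table.aac["SSP"].values, counts / counts.sum())


def test_contribution_from_direction(rng):
    m = _random_matrix(rng, "MKLIF")
    table = accumulate_contributions({"SSP": [m]}, direction="from")
    expected = np.zeros(20)
    for p, ref in enumerate("MKLIF"):
        expected[_AA_INDEX[ref]] += m.deltas[p].sum()
    np.testing.assert_allclose(table.contributions["SSP"].values, expected)


def test_contribution_empty_class_errors():
    with pytest.raises(ValueError, match="no ISM"):
        accumulate_contributions({"SSP": []})


def test_contribution_linearity(rng):
    m = _random_matrix(rng, "MKLIFACD")
    base = accumulate_contributions({"c": [m]}).contributions["c"].values
    scaled_m = IsmMatrix(m.record_id, m.reference_sequence, 3.0 * m.deltas, 0.5)
    scaled = accumulate_contributions({"c": [scaled_m]}).contributions["c"].values
    np.testing.assert_allclose(scaled, 3.0 * base)


# -- importance --------------------------------------------------------------
def test_importance_profile_cases(rng):
    assert np.all(importance_profile(IsmMatrix("z", "MK", np.zeros((2, 20)), 0.5)) == 0)
    deltas = np.zeros((1, 20))
    deltas[0, _AA_INDEX["L"]] = -0.19
    assert importance_profile(IsmMatrix("o", "M", deltas, 0.5))[0] \
        == pytest.approx(0.01)
    m = _random_matrix(rng, "MKLIFACD")
    want = np.array([np.abs(m.deltas[p]).sum() / 19 for p in range(8)])
    np.testing.assert_allclose(importance_profile(m), want)
    # |.| aggregation scales by |c|
    neg = IsmMatrix(m.record_id, m.reference_sequence, -2.0 * m.deltas, 0.5)
    np.testing.assert_allclose(importance_profile(neg), 2.0 * want)


def test_binning_identity_and_pairing():
    vals = np.arange(50.0)
    np.testing.assert_array_equal(bin_by_position_ratio(vals, 50), vals)
    vals = np.ones(100)
    np.testing.assert_array_equal(bin_by_position_ratio(vals, 50), np.full(50, 2.0))


def test_binning_short_sequence_has_missing_bins():
    out = bin_by_position_ratio(np.ones(10), 25)
    assert np.isnan(out).sum() == 15
    assert np.nansum(out) == pytest.approx(10.0)


def test_binning_rejects_bad_nbins():
    with pytest.raises(ValueError):
        bin_by_position_ratio(np.ones(5), 0)


def test_pooled_binning_matches_direct_loop(rng):
    mats = [_random_matrix(rng, "".join(rng.choice(list(AA_ALPHABET),
                                                   size=int(rng.integers(30, 80)))))
            for _ in range(10)]
    pooled = pooled_binned_importance(mats, 25)
    assert pooled.shape == (10, 25)
    for row, m in zip(pooled, mats):
        prof = importance_profile(m)
        L = len(prof)
        direct = np.full(25, np.nan)
        for p in range(L):
            b = min(p * 25 // L, 24)
            direct[b] = prof[p] if np.isnan(direct[b]) else direct[b] + prof[p]
        np.testing.assert_allclose(row, direct, equal_nan=True)


def test_residue_position_map_shapes(rng):
    mats = [_random_matrix(rng, "MKLIFACDEFGH") for _ in range(3)]
    raw = residue_position_map(mats, n_bins=50)
    assert raw.shape == (20, 50)
    norm = residue_position_map(mats, n_bins=50, normalize=True)
    occ = np.zeros(50)
    for m in mats:
        L = len(m.reference_sequence)
        for p in range(L):
            occ[min(p * 50 // L, 49)] += 1
    with np.errstate(invalid="ignore"):
        np.testing.assert_allclose(norm.values, raw.values / occ[None, :])


# -- clipping ----------------------------------------------------------------
def test_clip_record_arithmetic():
    rec = PeptideRecord("r", "AVCDEFGHIK", structure="HHHHHEEEEC")
    # forward clip at 0.5 on length 10 keeps residues 6..10
    fwd = clip_record(rec, 0.5, "forward")
    assert fwd.sequence == rec.sequence[5:]
    assert fwd.structure == rec.structure[5:]
    bwd = clip_record(rec, 0.3, "backward")
    assert bwd.sequence == rec.sequence[:7]
    assert bwd.structure == rec.structure[:7]
    same = clip_record(rec, 0.0, "forward")
    assert same.sequence == rec.sequence
    with pytest.raises(ValueError):
        clip_record(rec, 1.0, "forward")
    with pytest.raises(ValueError):
        clip_record(rec, 0.5, "sideways")


def test_clipping_ratio_zero_is_identity(small_dataset):
    model = CompositionScorer()
    curve = clipping_experiment(small_dataset, model, ratios=[0.0, 0.4],
                                direction="forward")
    _, preds = model.predict(small_dataset)
    unclipped = evaluate(small_dataset.labels(), preds)
    assert curve.reports[0] == unclipped
    assert curve.ratios == [0.0, 0.4]
    frame = curve.to_frame()
    assert list(frame["ratio"]) == [0.0, 0.4]


# -- motif extraction --------------------------------------------------------
def test_extract_motif_identical_windows_near_one_hot():
    seqs = ["KLIFK" + "A" * 15 for _ in range(6)]
    recs = [PeptideRecord(f"r{i}", s, structure="C" * len(s), label=1)
            for i, s in enumerate(seqs)]
    ds = PeptideDataset(recs)
    profiles = np.zeros((6, 10))
    profiles[:, 0:2] = 5.0  # importance concentrated in the first fifth
    motif = extract_motif(profiles, ds, window_bins=2, n_bins=10)
    assert motif.window_bins == (0, 2)
    pwm = motif.pwm.values
    np.testing.assert_allclose(pwm.sum(axis=1), 1.0, atol=1e-9)
    assert pwm.max(axis=1).min() > 0.9  # identical sources: near-one-hot
    for i, rec in enumerate(recs):
        assert motif.windows[rec.id] == (0, 4)


def test_extract_motif_window_length_validation():
    ds = PeptideDataset([PeptideRecord("a", "MKLIF")])
    with pytest.raises(ValueError, match="window_bins"):
        extract_motif(np.ones((1, 5)), ds, window_bins=9, n_bins=5)


def test_meme_export_parses(tmp_path):
    seqs = ["KLIFKAAAA"] * 4
    ds = PeptideDataset([PeptideRecord(f"r{i}", s) for i, s in enumerate(seqs)])
    profiles = np.ones((4, 9))
    motif = extract_motif(profiles, ds, window_bins=2, n_bins=9)
    out = tmp_path / "motif.meme"
    write_meme(motif, out)
    text = out.read_text().splitlines()
    assert text[0] == "MEME version 4"
    w_line = next(l for l in text if l.startswith("letter-probability"))
    width = int(w_line.split("w=")[1].split()[0])
    rows = [list(map(float, l.split())) for l in text[text.index(w_line) + 1:][:width]]
    for row in rows:
        assert len(row) == 20
        assert sum(row) == pytest.approx(1.0, abs=1e-4)


# -- latent projection -------------------------------------------------------
def test_pca_recovers_planar_data(rng):
    basis = np.linalg.qr(rng.normal(size=(8, 2)))[0]
    coords2 = rng.normal(size=(40, 2)) @ np.diag([3.0, 1.0])
    X = coords2 @ basis.T  # rank-2 cloud in 8-D
    out = project_latent(X, np.zeros(40), method="PCA", seed=0)
    got = out[["x", "y"]].values
    d_orig = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    d_proj = np.linalg.norm(got[:, None] - got[None, :], axis=-1)
    np.testing.assert_allclose(d_proj, d_orig, atol=1e-8)


def test_pca_variance_matches_eigendecomposition(rng):
    X = rng.normal(size=(50, 8))
    out = project_latent(X, np.zeros(50), method="PCA", seed=0)
    got = np.array([np.var(out["x"], ddof=1), np.var(out["y"], ddof=1)])
    evals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1][:2]
    np.testing.assert_allclose(got, evals, rtol=1e-8)


def test_tsne_runs_seeded_and_preserves_labels(rng):
    X = rng.normal(size=(30, 6))
    labels = np.arange(30) % 2
    a = project_latent(X, labels, method="tSNE", seed=3)
    b = project_latent(X, labels, method="tSNE", seed=3)
    pd.testing.assert_frame_equal(a, b)
    assert list(a["label"]) == list(labels)


def test_projection_input_validation(rng):
    with pytest.raises(ValueError):
        project_latent(rng.normal(size=(2, 5)), [0, 1], method="PCA")
    with pytest.raises(ValueError):
        project_latent(rng.normal(size=(5, 1)), [0] * 5, method="PCA")
    with pytest.raises(ValueError):
        project_latent(rng.normal(size=(5, 3)), [0] * 5, method="umap")
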
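"""Word identification from reconstructed spectrograms.

A reconstructed word is compared to every candidate word with a
dynamic-time-warping similarity: DTW aligns the two spectrograms' frame
sequences (cost = 1 - per-frame Pearson correlation between frequency
columns), and the similarity is the Pearson correlation of the aligned,
vectorized spectrograms. The percentile rank of the correct word among the
candidates quantifies identification; chance level is a mean rank of 0.5.
A randomization test (shuffling the reconstruction-to-word pairing)
provides the null for the median rank, and an ROC summarizes the
separability of matched versus mismatched pairs. Identification is run on
box-smoothed spectrograms (500 ms x 2 octaves), while the pairwise
similarity matrices are computed before smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import rankdata

from ._dtw import dtw_align
from .audio_frontend import AuditorySpectrogram
from .exceptions import InvalidConfigError, InvalidInputError

__all__ = [
    "WordSet",
    "IdentificationResult",
    "smooth_spectrogram",
    "dtw_similarity",
    "identification_rank",
    "identification_suite",
    "chance_identification_ranks",
]

SMOOTH_T_WINDOW_S = 0.5
SMOOTH_F_WINDOW_OCT = 2.0


@dataclass
class WordSet:
    """Labelled candidate word spectrograms sharing one frequency axis."""

    labels: list
    spectrograms: list

    def __post_init__(self):
        if len(self.labels) != len(self.spectrograms):
            raise InvalidInputError("labels and spectrograms must align")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidInputError("word labels must be unique")
        axes = {tuple(np.round(s.freq_centers_hz, 6)) for s in self.spectrograms}
        if len(axes) > 1:
            raise InvalidInputError("candidate words must share a frequency axis")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InvalidInputError(f"label {label!r} not in candidate set") from None


@dataclass
class IdentificationResult:
    ranks: np.ndarray
    median_rank: float
    p_value: float
    p_conservative: float
    roc: tuple  # (fpr, tpr)
    similarity_actual: np.ndarray
    similarity_recon: np.ndarray
    similarity_correlation: float


def smooth_spectrogram(
    s: AuditorySpectrogram,
    t_window_s: float = SMOOTH_T_WINDOW_S,
    f_window_oct: float = SMOOTH_F_WINDOW_OCT,
) -> AuditorySpectrogram:
    """2-D moving average with edge truncation (window shrinks at borders)."""
    if t_window_s <= 0 or f_window_oct <= 0:
        raise InvalidConfigError("smoothing windows must be positive")
    w_t = max(1, int(round(t_window_s * s.frame_rate_hz)))
    w_f = max(1, int(round(f_window_oct / s.channel_spacing_octaves)) + 1)
    if w_t > s.n_frames and w_f > s.n_freq:
        raise InvalidConfigError("smoothing window exceeds the signal in both axes")
    w_t = min(w_t, s.n_frames)
    w_f = min(w_f, s.n_freq)
    box = np.ones((w_f, w_t))
    num = signal.fftconvolve(s.values, box, mode="same")
    den = signal.fftconvolve(np.ones_like(s.values), box, mode="same")
    return AuditorySpectrogram(np.clip(num / den, 0, None),
                               s.freq_centers_hz, s.frame_rate_hz)


def _frame_correlation_cost(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """cost[i, j] = 1 - corr(A[:, i], B[:, j]); flat frames score zero corr."""
    def zscore(M):
        mu = M.mean(axis=0, keepdims=True)
        sd = M.std(axis=0, keepdims=True)
        out = np.where(sd > 0, (M - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        return out
    Az, Bz = zscore(A), zscore(B)
    corr = (Az.T @ Bz) / A.shape[0]
    return 1.0 - corr


def dtw_similarity(a: AuditorySpectrogram, b: AuditorySpectrogram) -> float:
    """DTW-aligned correlation between two spectrograms."""
    if a.n_frames == 0 or b.n_frames == 0:
        raise InvalidInputError("empty spectrogram")
    if a.n_freq != b.n_freq:
        raise InvalidInputError("spectrograms must share a frequency axis")
    cost = _frame_correlation_cost(a.values, b.values)
    pi, pj, _ = dtw_align(cost)
    x = a.values[:, pi].ravel()
    y = b.values[:, pj].ravel()
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _rank_from_scores(scores: np.ndarray, correct_idx: int) -> float:
    """Percentile rank: candidates strictly below count 1, ties count 0.5."""
    s0 = scores[correct_idx]
    others = np.delete(scores, correct_idx)
    below = np.sum(others < s0) + 0.5 * np.sum(others == s0)
    return float(below / (scores.size - 1))


def identification_rank(
    target_recon: AuditorySpectrogram, truth_label, candidates: WordSet
) -> float:
    """Percentile rank of the correct word by DTW similarity.

    1.0 means the reconstruction matched the correct word best among all
    candidates; 0.0 means the correct word scored lowest.
    """
    idx = candidates.index_of(truth_label)
    scores = np.array(
        [dtw_similarity(target_recon, s) for s in candidates.spectrograms]
    )
    return _rank_from_scores(scores, idx)


def _row_percentile_ranks(S: np.ndarray) -> np.ndarray:
    """rank[i, j] = percentile rank of entry j within row i (ties at 0.5)."""
    n = S.shape[1]
    out = np.empty_like(S)
    for i in range(S.shape[0]):
        out[i] = (rankdata(S[i], method="average") - 1.0) / (n - 1)
    return out


def _roc_curve(scores_pos: np.ndarray, scores_neg: np.ndarray):
    thresholds = np.unique(np.concatenate([scores_pos, scores_neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for th in thresholds:
        tpr.append(np.mean(scores_pos >= th))
        fpr.append(np.mean(scores_neg >= th))
    return np.asarray(fpr), np.asarray(tpr)


def identification_suite(
    recons,
    truth_labels,
    candidates: WordSet,
    n_shuffles: int = 10000,
    seed: int | None = None,
    smooth: bool = True,
) -> IdentificationResult:
    """Full identification analysis for a set of reconstructions.

    Computes per-word identification ranks (on smoothed spectrograms by
    default), the median rank with a pair-shuffling randomization p-value,
    an ROC over matched versus mismatched similarity scores, and the
    pairwise similarity matrices of actual words and of reconstructions
    against actual words (both computed before smoothing) together with
    their correlation over distinct word pairs.
    """
    n = candidates.n
    if len(recons) != len(truth_labels):
        raise InvalidInputError("one truth label per reconstruction required")
    truth_idx = np.array([candidates.index_of(l) for l in truth_labels])

    cand_raw = candidates.spectrograms
    if smooth:
        cand_id = [smooth_spectrogram(s) for s in cand_raw]
        recons_id = [smooth_spectrogram(s) for s in recons]
    else:
        cand_id, recons_id = cand_raw, list(recons)

    # similarity of reconstructions to candidates (identification space)
    S_id = np.array(
        [[dtw_similarity(r, c) for c in cand_id] for r in recons_id]
    )
    rank_matrix = _row_percentile_ranks(S_id)
    ranks = rank_matrix[np.arange(len(recons)), truth_idx]
    median = float(np.median(ranks))

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        perm = rng.permutation(n)[: len(recons)]
        null[k] = np.median(rank_matrix[np.arange(len(recons)), perm])
    k_ge = int(np.sum(null >= median))
    p = k_ge / n_shuffles
    p_cons = (k_ge + 1) / (n_shuffles + 1)

    pos = S_id[np.arange(len(recons)), truth_idx]
    neg_mask = np.ones_like(S_id, dtype=bool)
    neg_mask[np.arange(len(recons)), truth_idx] = False
    fpr, tpr = _roc_curve(pos, S_id[neg_mask])

    # pairwise similarity matrices, pre-smoothing
    sim_actual = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim_actual[i, j] = sim_actual[j, i] = dtw_similarity(
                cand_raw[i], cand_raw[j]
            )
    recons_raw = list(recons)
    sim_recon = np.array(
        [[dtw_similarity(r, c) for c in cand_raw] for r in recons_raw]
    )
    off = ~np.eye(n, dtype=bool)
    if len(recons) == n:
        sim_corr = float(
            np.corrcoef(sim_actual[off], sim_recon[off])[0, 1]
        )
    else:
        sim_corr = np.nan

    return IdentificationResult(
        ranks=ranks,
        median_rank=median,
        p_value=p,
        p_conservative=p_cons,
        roc=(fpr, tpr),
        similarity_actual=sim_actual,
        similarity_recon=sim_recon,
        similarity_correlation=sim_corr,
    )


def chance_identification_ranks(
    candidates: WordSet,
    n_targets: int,
    seed: int | None = None,
    smooth: bool = True,
    duration_range_s: tuple = (0.3, 1.0),
) -> np.ndarray:
    """Identification ranks when reconstructions carry no word information.

    Each target substitutes an independent random spectrogram (white
    nonnegative values, duration drawn from ``duration_range_s``) for the
    reconstruction; truth labels cycle through the candidate words so every
    word serves as the target equally often. The expected mean rank is 0.5.
    """
    if candidates.n < 2:
        raise InvalidInputError("need at least two candidate words")
    rng = np.random.default_rng(seed)
    cand = (
        [smooth_spectrogram(s) for s in candidates.spectrograms]
        if smooth
        else candidates.spectrograms
    )
    template = candidates.spectrograms[0]
    fr = template.frame_rate_hz
    ranks = np.empty(n_targets)
    for k in range(n_targets):
        dur = rng.uniform(*duration_range_s)
        vals = np.abs(rng.standard_normal((template.n_freq, int(round(dur * fr)))))
        recon = AuditorySpectrogram(vals, template.freq_centers_hz, fr)
        if smooth:
            recon = smooth_spectrogram(recon)
        scores = np.array([dtw_similarity(recon, c) for c in cand])
        ranks[k] = _rank_from_scores(scores, k % candidates.n)
    return ranks
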
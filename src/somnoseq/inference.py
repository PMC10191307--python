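"""Overlapping-window voting: one label per epoch from windowed predictions.

With a stride-1 sliding window of length L, every interior epoch is
predicted L times (12 by default); the first and last L-1 epochs receive
fewer votes. The night-level label of each epoch is the mode of its votes,
with ties broken by the highest mean predicted probability among the tied
classes across the contributing windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import NormStats, SleepStager, make_windows
from .stages import Hypnogram, StageScheme


@dataclass
class VoteTable:
    """Per-epoch vote lists from overlapping windows."""

    window_ids: list[np.ndarray]   # per epoch, contributing window indices
    labels: list[np.ndarray]       # per epoch, per-window argmax labels
    probs: list[np.ndarray]        # per epoch, (votes, K) probability rows
    n_classes: int

    def __len__(self):
        return len(self.labels)

    def counts(self) -> np.ndarray:
        return np.array([len(v) for v in self.labels])


def collect_votes(probs: np.ndarray, starts: np.ndarray,
                  n_epochs: int | None = None) -> VoteTable:
    """Group per-window per-epoch predictions by absolute epoch index.

    ``probs`` is (B, L, K) from the model; ``starts`` maps window b to its
    first epoch, as returned by :func:`somnoseq.model.make_windows`.
    """
    probs = np.asarray(probs)
    starts = np.asarray(starts, dtype=np.int64)
    if probs.ndim != 3 or probs.shape[0] != starts.size:
        raise ValueError("probability tensor does not match the window index map")
    B, L, K = probs.shape
    if n_epochs is None:
        n_epochs = int(starts.max()) + L
    win_labels = probs.argmax(axis=-1)
    wids: list[list[int]] = [[] for _ in range(n_epochs)]
    labs: list[list[int]] = [[] for _ in range(n_epochs)]
    prows: list[list[np.ndarray]] = [[] for _ in range(n_epochs)]
    for b in range(B):
        for t in range(L):
            e = starts[b] + t
            wids[e].append(b)
            labs[e].append(int(win_labels[b, t]))
            prows[e].append(probs[b, t])
    return VoteTable([np.array(w, dtype=np.int64) for w in wids],
                     [np.array(l, dtype=np.int64) for l in labs],
                     [np.array(p) if p else np.empty((0, K)) for p in prows],
                     K)


def mode_vote(votes: VoteTable, scheme: StageScheme,
              epoch_s: float = 30.0) -> Hypnogram:
    """Most frequent vote per epoch; probability-mean tie-break."""
    if any(len(v) == 0 for v in votes.labels):
        raise ValueError("every epoch needs at least one vote")
    out = np.empty(len(votes), dtype=np.int64)
    for e, labs in enumerate(votes.labels):
        counts = np.bincount(labs, minlength=votes.n_classes)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if tied.size == 1:
            out[e] = tied[0]
        else:
            # mean predicted probability of each tied class across the
            # epoch's contributing windows; earlier class wins exact ties
            mean_p = votes.probs[e].mean(axis=0)[tied]
            out[e] = tied[np.argmax(mean_p)]
    return Hypnogram(out, scheme, epoch_s)


def predict_series(model: SleepStager, channels: np.ndarray, scheme: StageScheme,
                   norm: NormStats | None = None, stride: int = 1,
                   epoch_s: float = 30.0,
                   return_probs: bool = False):
    """Stage a full night: window, forward, vote.

    ``channels`` is the raw (C, N) matrix; ``norm`` is the training-split
    normalization. Returns the predicted :class:`Hypnogram` (and the mean
    per-epoch probability matrix when ``return_probs``).
    """
    x = norm.apply(channels) if norm is not None else channels
    windows, starts = make_windows(x, model.config.window, stride)
    probs = model.predict_proba(windows)
    votes = collect_votes(probs, starts, n_epochs=channels.shape[1])
    hyp = mode_vote(votes, scheme, epoch_s)
    if return_probs:
        mean_probs = np.vstack([p.mean(axis=0) for p in votes.probs])
        return hyp, mean_probs
    return hyp
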
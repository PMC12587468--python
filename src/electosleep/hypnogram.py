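"""Hypnograms, transition matrices, top-k Viterbi smoothing and bout statistics.

A :class:`Hypnogram` holds one label per non-overlapping 2 s window, optionally
with per-state probabilities (a "hypnodensity"), a smoothed label track and a
per-window smoothing confidence.  Temporal smoothing combines the classifier's
per-window state probabilities with empirical state-transition statistics via a
k-best (list) Viterbi dynamic program; bout statistics quantify sleep
architecture (fragmentation) from the smoothed track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import STATES, STATE_NAMES, UNKNOWN, state_name, names_to_labels

N_STATES = len(STATES)


@dataclass
class Hypnogram:
    """Per-window sleep-wake labels with optional probabilities and smoothing.

    Parameters
    ----------
    labels : (n,) int array of state codes (``UNKNOWN`` allowed)
    window_s : window duration in seconds (2.0 throughout this package)
    probabilities : optional (n, 3) array, rows on the simplex for labeled
        windows; rows of NaN for UNKNOWN windows
    smoothed : optional (n,) int array, the Viterbi-smoothed track
    confidence : optional (n,) array in [1/k, 1], the fraction of the top-k
        paths agreeing with the top-1 state at each window
    """

    labels: np.ndarray
    window_s: float = 2.0
    probabilities: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.shape != (len(self.labels), N_STATES):
                raise ValueError("probabilities must be (n_windows, 3)")
            ok = ~np.isnan(p).any(axis=1)
            if ok.any():
                s = p[ok].sum(axis=1)
                if (p[ok] < -1e-12).any() or np.abs(s - 1).max() > 1e-6:
                    raise ValueError("probability rows must be non-negative and sum to 1")
            self.probabilities = p

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready frame: window_index, start_s, end_s, label[, p_*, smoothed...]."""
        n = len(self)
        df = pd.DataFrame(
            {
                "window_index": np.arange(n),
                "start_s": np.arange(n) * self.window_s,
                "end_s": (np.arange(n) + 1) * self.window_s,
                "label": [state_name(int(c)) for c in self.labels],
            }
        )
        if self.probabilities is not None:
            for j, nm in enumerate(STATE_NAMES):
                df[f"p_{nm}"] = self.probabilities[:, j]
        if self.smoothed is not None:
            df["smoothed_label"] = [state_name(int(c)) for c in self.smoothed]
        if self.confidence is not None:
            df["confidence"] = self.confidence
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Hypnogram":
        df = pd.read_csv(path)
        labels = names_to_labels(df["label"])
        window_s = float(df["end_s"].iloc[0] - df["start_s"].iloc[0]) if len(df) else 2.0
        probs = None
        cols = [f"p_{nm}" for nm in STATE_NAMES]
        if all(c in df.columns for c in cols):
            probs = df[cols].to_numpy(dtype=float)
        smoothed = None
        if "smoothed_label" in df.columns:
            smoothed = names_to_labels(df["smoothed_label"])
        conf = df["confidence"].to_numpy(dtype=float) if "confidence" in df.columns else None
        return cls(labels, window_s=window_s, probabilities=probs,
                   smoothed=smoothed, confidence=conf)


@dataclass
class TransitionMatrix:
    """Row-stochastic 3x3 state-transition probabilities over (wake, NREM, REM)."""

    probs: np.ndarray
    smoothing: float = 1.0
    source: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_STATES, N_STATES):
            raise ValueError("transition matrix must be 3x3")
        if (self.probs < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if np.abs(self.probs.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("transition matrix rows must sum to 1")

    def stationary(self) -> np.ndarray:
        """Stationary distribution: left eigenvector of eigenvalue 1, normalized."""
        w, v = np.linalg.eig(self.probs.T)
        i = int(np.argmin(np.abs(w - 1)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class Bout:
    """A maximal run of consecutive windows in one state."""

    state: int
    start: int
    length: int
    window_s: float = 2.0

    @property
    def duration_s(self) -> float:
        return self.length * self.window_s


def estimate_transitions(label_seqs, smoothing: float = 1.0) -> TransitionMatrix:
    """Estimate the 3x3 transition matrix from labeled window sequences.

    Consecutive (s_t, s_{t+1}) pairs are counted across all sequences; an
    UNKNOWN window breaks adjacency.  Counts are add-constant smoothed and
    row-normalized.  Add-one smoothing (default) guarantees strictly positive
    entries so that rare transitions (REM->wake) remain representable.
    """
    if isinstance(label_seqs, (np.ndarray, Hypnogram)) or (
        len(label_seqs) and np.isscalar(label_seqs[0])
    ):
        label_seqs = [label_seqs]
    counts = np.zeros((N_STATES, N_STATES))
    for seq in label_seqs:
        lab = seq.labels if isinstance(seq, Hypnogram) else np.asarray(seq, dtype=np.int64)
        a, b = lab[:-1], lab[1:]
        ok = (a != UNKNOWN) & (b != UNKNOWN)
        np.add.at(counts, (a[ok], b[ok]), 1)
    if counts.sum() == 0:
        raise ValueError("no consecutive labeled window pairs to estimate transitions from")
    counts = counts + smoothing
    rows = counts.sum(axis=1, keepdims=True)
    if (rows == 0).any():
        # only possible with smoothing == 0 and an unseen state
        rows = np.where(rows == 0, 1.0, rows)
        probs = counts / rows
        probs[np.asarray(counts.sum(axis=1) == 0)] = np.eye(N_STATES)[
            np.asarray(counts.sum(axis=1) == 0).nonzero()[0]
        ]
    else:
        probs = counts / rows
    return TransitionMatrix(probs, smoothing=smoothing, source="estimate_transitions")


def viterbi_topk(
    probabilities: np.ndarray,
    transitions: TransitionMatrix,
    k: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """k-best list Viterbi decoding.

    Finds the ``k`` state sequences maximizing
    ``sum_t log p(s_t | window t) + sum_{t<T-1} log T(s_t, s_{t+1})``
    plus the log initial prior (the transition matrix's stationary
    distribution), in non-increasing score order.

    Parameters
    ----------
    probabilities : (T, 3) per-window state probabilities, used directly as
        emission likelihoods
    transitions : TransitionMatrix
    k : number of sequences to return

    Returns
    -------
    paths : (k', T) int array, k' = min(k, 3**T)
    scores : (k',) path log-scores, non-increasing
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2 or p.shape[1] != N_STATES:
        raise ValueError("probabilities must be (T, 3)")
    if k < 1:
        raise ValueError("k must be >= 1")
    T = p.shape[0]
    with np.errstate(divide="ignore"):
        logem = np.log(p)
        logtr = np.log(transitions.probs)
        logpi = np.log(transitions.stationary())

    # scores[s] : list of (score, backpointer) for the k best paths ending in s
    # bp = (prev_state, rank_in_prev_state) or None at t=0
    scores = np.full((T, N_STATES, k), -np.inf)
    back = np.zeros((T, N_STATES, k, 2), dtype=np.int64)
    nkept = np.zeros((T, N_STATES), dtype=np.int64)

    first = logpi + logem[0]
    if not np.isfinite(first).any():
        raise ValueError("all states have zero probability at window 0")
    scores[0, :, 0] = first
    nkept[0, :] = 1

    for t in range(1, T):
        for s in range(N_STATES):
            # candidates: best paths per predecessor + transition + emission
            cand_scores = []
            cand_back = []
            for sp in range(N_STATES):
                m = nkept[t - 1, sp]
                if m == 0:
                    continue
                cs = scores[t - 1, sp, :m] + logtr[sp, s] + logem[t, s]
                cand_scores.append(cs)
                cand_back.append(np.stack([np.full(m, sp), np.arange(m)], axis=1))
            cs = np.concatenate(cand_scores)
            cb = np.concatenate(cand_back)
            finite = np.isfinite(cs)
            cs, cb = cs[finite], cb[finite]
            order = np.argsort(-cs, kind="stable")[:k]
            m = len(order)
            scores[t, s, :m] = cs[order]
            back[t, s, :m] = cb[order]
            nkept[t, s] = m
        if nkept[t].sum() == 0:
            raise ValueError(f"zero-probability deadlock at window {t}: all paths impossible")

    # gather final candidates across states and backtrack
    finals = []
    for s in range(N_STATES):
        for r in range(nkept[T - 1, s]):
            finals.append((scores[T - 1, s, r], s, r))
    finals.sort(key=lambda x: -x[0])
    finals = finals[:k]

    paths = np.empty((len(finals), T), dtype=np.int64)
    out_scores = np.empty(len(finals))
    for i, (sc, s, r) in enumerate(finals):
        out_scores[i] = sc
        st, rk = s, r
        for t in range(T - 1, -1, -1):
            paths[i, t] = st
            if t > 0:
                st, rk = back[t, st, rk]
    return paths, out_scores


def smooth(
    hypnogram: Hypnogram,
    transitions: TransitionMatrix,
    k: int = 10,
) -> Hypnogram:
    """Viterbi-smooth a hypnogram's probability track.

    The smoothed label at each window is the top-1 path's state; the
    confidence is the fraction of the top-k paths agreeing with it.  UNKNOWN
    windows (NaN probability rows) are bridged with uniform emissions so the
    path remains continuous across gaps.
    """
    if hypnogram.probabilities is None:
        raise ValueError("smoothing requires per-window probabilities")
    p = hypnogram.probabilities.copy()
    gap = np.isnan(p).any(axis=1)
    p[gap] = 1.0 / N_STATES
    paths, _scores = viterbi_topk(p, transitions, k=k)
    top1 = paths[0]
    conf = (paths == top1[None, :]).mean(axis=0)
    return Hypnogram(
        labels=hypnogram.labels,
        window_s=hypnogram.window_s,
        probabilities=hypnogram.probabilities,
        smoothed=top1,
        confidence=conf,
    )


def find_bouts(labels: np.ndarray, window_s: float = 2.0) -> list[Bout]:
    """Maximal-run decomposition of a label sequence (UNKNOWN runs skipped)."""
    labels = np.asarray(labels, dtype=np.int64)
    bouts: list[Bout] = []
    n = len(labels)
    i = 0
    while i < n:
        if labels[i] == UNKNOWN:
            i += 1
            continue
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        bouts.append(Bout(int(labels[i]), i, j - i, window_s))
        i = j
    return bouts


def architecture_stats(
    hypnogram: Hypnogram,
    interval: tuple[float, float] | None = None,
    use_smoothed: bool = True,
) -> dict:
    """Per-state sleep-architecture summary: time share, bout count, durations.

    Parameters
    ----------
    hypnogram : labeled (ideally smoothed) hypnogram
    interval : optional (start_s, end_s) restriction, half-open
    use_smoothed : prefer the smoothed track when present

    Returns
    -------
    dict with one entry per state name:
    ``{percent_time, n_bouts, mean_bout_s, median_bout_s}`` plus
    ``n_labeled_windows``.
    """
    labels = hypnogram.smoothed if (use_smoothed and hypnogram.smoothed is not None) \
        else hypnogram.labels
    labels = np.asarray(labels, dtype=np.int64)
    if interval is not None:
        lo = int(np.ceil(interval[0] / hypnogram.window_s))
        hi = int(np.floor(interval[1] / hypnogram.window_s))
        labels = labels[lo:hi]
    labeled = labels[labels != UNKNOWN]
    out: dict = {"n_labeled_windows": int(len(labeled))}
    if len(labeled) == 0:
        warnings.warn("no labeled windows in requested interval; zero statistics")
        for nm in STATE_NAMES:
            out[nm] = {"percent_time": 0.0, "n_bouts": 0,
                       "mean_bout_s": 0.0, "median_bout_s": 0.0}
        return out
    bouts = find_bouts(labels, hypnogram.window_s)
    for code, nm in zip(STATES, STATE_NAMES):
        durs = np.array([b.duration_s for b in bouts if b.state == code])
        out[nm] = {
            "percent_time": 100.0 * float((labeled == code).sum()) / len(labeled),
            "n_bouts": int(len(durs)),
            "mean_bout_s": float(durs.mean()) if len(durs) else 0.0,
            "median_bout_s": float(np.median(durs)) if len(durs) else 0.0,
        }
    return out
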
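"""Condition comparisons of power/synchrony features via per-feature t-tests
and corrected harmonic-mean p-values.

Subjects are the statistical unit: for each subject and state the features
are first averaged over that state's valid windows.  Each of the d features
(1,856 for 8 regions x 29 bins) is compared between groups with an
independent two-sided Welch t-test; the d p-values are combined into one
"headline" p-value per state with the harmonic mean p (HMP) and its
asymptotically exact heavy-tailed (Landau) correction, which controls the
familywise error rate at approximately alpha even under dependence between
tests.  Individual features are displayed at unadjusted alpha = 0.01,
independent of the HMP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

from .features import FeatureTensor, flatten
from .hypnogram import Hypnogram
from .states import STATES, STATE_NAMES, UNKNOWN

#: Landau location offset for the asymptotically exact HMP tail
_LANDAU_OFFSET = 0.874367040387922


@dataclass
class ConditionSummary:
    """Per-subject, per-state mean feature vectors.

    ``means`` maps state name -> length-d vector (states with zero windows
    are omitted).
    """

    subject_id: str
    means: dict[str, np.ndarray]
    n_windows: dict[str, int] = field(default_factory=dict)
    condition: str = ""


@dataclass
class GroupComparison:
    """Per-feature and headline statistics for one state."""

    state: str
    t: np.ndarray
    p: np.ndarray
    mean_difference: np.ndarray      # group_a mean - group_b mean
    hmp: float
    headline_p: float
    display_mask: np.ndarray         # p < alpha_display
    alpha_display: float = 0.01
    zero_variance: np.ndarray | None = None


def state_mean_features(
    tensor: FeatureTensor,
    hypnogram: Hypnogram,
    use_smoothed: bool = True,
    condition: str = "",
) -> ConditionSummary:
    """Average flattened features over each state's valid labeled windows."""
    labels = hypnogram.smoothed if (use_smoothed and hypnogram.smoothed is not None) \
        else hypnogram.labels
    labels = np.asarray(labels, dtype=np.int64)
    X = flatten(tensor)
    n = min(len(labels), X.shape[0])
    labels, X = labels[:n], X[:n]
    valid = tensor.valid_mask[:n]
    means: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for s, nm in zip(STATES, STATE_NAMES):
        sel = (labels == s) & valid
        if not sel.any():
            warnings.warn(f"state {nm} has no valid windows; omitted from summary")
            continue
        means[nm] = X[sel].mean(axis=0)
        counts[nm] = int(sel.sum())
    return ConditionSummary(tensor.subject_id, means, counts, condition)


def cosine_similarity(vec_a: np.ndarray, vec_b: np.ndarray) -> float:
    """Cosine of the angle between two feature vectors, in [-1, 1]."""
    a = np.asarray(vec_a, dtype=float).ravel()
    b = np.asarray(vec_b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def feature_ttests(group_a: np.ndarray, group_b: np.ndarray):
    """Independent two-sided Welch t-tests, one per feature column.

    Parameters are subjects x d matrices of within-subject state means.
    Features with zero variance in both groups and equal means get t = 0,
    p = 1, and a flag.
    """
    A = np.asarray(group_a, dtype=float)
    B = np.asarray(group_b, dtype=float)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ between groups")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance features trigger a precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sst.ttest_ind(A, B, axis=0, equal_var=False)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    # exact zeros are unreachable for finite t, but clip defensively into (0, 1]
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    diff = A.mean(axis=0) - B.mean(axis=0)
    return t, p, diff, degenerate


def harmonic_mean_p(
    p_values: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Weighted harmonic mean p-value and its corrected (headline) tail.

    HMP = (sum w_i) / (sum w_i / p_i); the headline p is the asymptotically
    exact tail probability of 1/HMP under a Landau distribution with location
    log(L) + 0.8744 and scale pi/2 (L = number of tests), valid for the
    uniform-weight harmonic mean and robust to dependence between tests.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if len(p) == 0:
        raise ValueError("no p-values")
    if (p <= 0).any():
        raise ValueError("p-values must be in (0, 1]: zero makes the reciprocal undefined")
    if (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    if weights is None:
        w = np.full(len(p), 1.0 / len(p))
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
    hmp = float(w.sum() / np.sum(w / p))
    L = len(p)
    headline = float(
        sst.landau.sf(1.0 / hmp, loc=np.log(L) + _LANDAU_OFFSET, scale=np.pi / 2)
    )
    return hmp, min(max(headline, 0.0), 1.0)


def compare_conditions(
    summaries_a: list[ConditionSummary],
    summaries_b: list[ConditionSummary],
    alpha_display: float = 0.01,
) -> dict[str, GroupComparison]:
    """Full pipeline per state: t-tests -> headline HMP -> display mask.

    Returns one :class:`GroupComparison` per state present in >= 2 subjects
    of each group.  The mean-difference sign convention is group_a - group_b.
    """
    out: dict[str, GroupComparison] = {}
    for nm in STATE_NAMES:
        A = np.stack([s.means[nm] for s in summaries_a if nm in s.means]) \
            if any(nm in s.means for s in summaries_a) else None
        B = np.stack([s.means[nm] for s in summaries_b if nm in s.means]) \
            if any(nm in s.means for s in summaries_b) else None
        if A is None or B is None or A.shape[0] < 2 or B.shape[0] < 2:
            warnings.warn(f"state {nm}: fewer than 2 subjects per group; skipped")
            continue
        t, p, diff, degen = feature_ttests(A, B)
        hmp, headline = harmonic_mean_p(p)
        out[nm] = GroupComparison(
            state=nm, t=t, p=p, mean_difference=diff,
            hmp=hmp, headline_p=headline,
            display_mask=p < alpha_display, alpha_display=alpha_display,
            zero_variance=degen,
        )
    return out
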
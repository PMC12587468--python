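"""Supervised autoencoder (SAE) sleep-wake classifier with electome factors.

The model maps a window's d-dimensional power/synchrony feature vector x to 32
latent "electome scores" z = A x + b.  The first three scores, scaled by a
3-entry diagonal matrix C, are the wake/NREM/REM logits; all 32 scores,
rectified with a softplus, reconstruct x through a non-negative matrix H whose
rows are the "electome factors" (vectorized regions x regions x frequencies
tensors).  Training minimizes

    cross_entropy(C(Ax+b), y) + mu * || H^T softplus(Ax+b) - x ||_2

averaged over windows, by Adam with H projected onto the non-negative orthant
after every step.  Gradients are computed analytically (see ``_loss_and_grads``)
and are checked against central finite differences in the test suite.

Model selection follows leave-one-mouse-out nested cross-validation: the inner
loop scores each mu on shuffled train/validation mouse splits by validation
balanced accuracy, the outer loop reports the unbiased test-mouse accuracy,
and the chosen mu is refit on all mice for the final model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .features import FeatureTensor
from .hypnogram import Hypnogram
from .states import STATES, STATE_NAMES, UNKNOWN, state_name

N_STATES = 3
LATENT_DIM = 32          # 3 supervised + 29 unsupervised factors
N_SUPERVISED = 3


@dataclass
class TrainingConfig:
    """Optimizer and model-selection settings (exposed, not claimed)."""

    mu_grid: tuple[float, ...] = (1e-1, 1e-2, 1e-3)
    epochs: int = 300
    batch_size: int = 256
    learning_rate: float = 1e-3
    patience: int = 20
    seed: int = 0
    squared_reconstruction: bool = False
    n_inner_splits: int = 3

    def __post_init__(self) -> None:
        if not self.mu_grid or any(m <= 0 for m in self.mu_grid):
            raise ValueError("mu grid must be non-empty with mu > 0")


@dataclass
class ElectomeModel:
    """Trained SAE parameters plus region/frequency metadata.

    ``A`` (32 x d), ``b`` (32,), ``c_diag`` (3,) — the nonzero entries of the
    diagonal classification matrix C — ``H`` (32 x d, entrywise >= 0), and the
    reconstruction weight ``mu``.
    """

    A: np.ndarray
    b: np.ndarray
    c_diag: np.ndarray
    H: np.ndarray
    mu: float
    regions: list[str] = field(default_factory=list)
    freqs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.A.shape[0] != LATENT_DIM or self.H.shape != self.A.shape:
            raise ValueError(f"A and H must be {LATENT_DIM} x d")
        if (self.H < 0).any():
            raise ValueError("H must be non-negative entrywise")
        if self.c_diag.shape != (N_STATES,):
            raise ValueError("C has exactly three diagonal entries")
        if self.mu <= 0:
            raise ValueError("mu must be positive")

    @property
    def d(self) -> int:
        return self.A.shape[1]

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Electome scores z = A x + b for each row of X."""
        return X @ self.A.T + self.b

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.scores(X)[:, :N_SUPERVISED] * self.c_diag


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


def _loss_and_grads(
    params: dict[str, np.ndarray],
    X: np.ndarray,
    Y: np.ndarray,
    mu: float,
    squared: bool = False,
    want_grads: bool = True,
):
    """Mean objective over a batch and its analytic parameter gradients.

    X : (B, d) features; Y : (B, 3) one-hot labels.
    Returns (total, prediction_term, reconstruction_term[, grads]).
    """
    A, b, c, H = params["A"], params["b"], params["c_diag"], params["H"]
    B = X.shape[0]
    Z = X @ A.T + b                      # (B, 32)
    logits = Z[:, :N_SUPERVISED] * c
    P = _softmax(logits)
    ce = -np.log(np.clip(np.sum(P * Y, axis=1), 1e-300, None))
    S = _softplus(Z)                     # (B, 32)
    Rres = S @ H - X                     # (B, d)
    if squared:
        rec = np.sum(Rres ** 2, axis=1)
    else:
        rec = np.sqrt(np.sum(Rres ** 2, axis=1))
    pred_term = float(ce.mean())
    rec_term = float(rec.mean())
    total = pred_term + mu * rec_term
    if not want_grads:
        return total, pred_term, rec_term

    dlogits = (P - Y) / B                # (B, 3)
    if squared:
        dR = (mu / B) * 2.0 * Rres
    else:
        rho = np.maximum(rec, 1e-12)
        dR = (mu / B) * Rres / rho[:, None]
    dS = dR @ H.T                        # (B, 32)
    dZ = dS * expit(Z)
    dZ[:, :N_SUPERVISED] += dlogits * c
    grads = {
        "A": dZ.T @ X,
        "b": dZ.sum(axis=0),
        "c_diag": np.sum(dlogits * Z[:, :N_SUPERVISED], axis=0),
        "H": S.T @ dR,
    }
    return total, pred_term, rec_term, grads


def objective(
    model: ElectomeModel, x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """Evaluate the SAE objective on one window or a batch.

    Returns (total, prediction_term, reconstruction_term); the total is
    prediction + mu * reconstruction, batch-aggregated by the mean of
    per-window losses.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    Y = np.atleast_2d(np.asarray(y, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(f"feature dimension {X.shape[1]} != model d={model.d}")
    if Y.shape != (X.shape[0], N_STATES):
        raise ValueError("labels must be one-hot over the three states")
    params = {"A": model.A, "b": model.b, "c_diag": model.c_diag, "H": model.H}
    total, pred, rec = _loss_and_grads(params, X, Y, model.mu, want_grads=False)
    return total, pred, rec


def _one_hot(labels: np.ndarray) -> np.ndarray:
    Y = np.zeros((len(labels), N_STATES))
    Y[np.arange(len(labels)), labels] = 1.0
    return Y


def _stack_labeled(features, labels):
    """Concatenate per-mouse (X, y), dropping UNKNOWN windows."""
    Xs, ys = [], []
    for X, y in zip(features, labels):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        keep = y != UNKNOWN
        Xs.append(X[keep])
        ys.append(y[keep])
    return np.concatenate(Xs), np.concatenate(ys)


def fit(
    features,
    labels,
    config: TrainingConfig,
    mu: float | None = None,
    val_features=None,
    val_labels=None,
) -> ElectomeModel:
    """Train the SAE by Adam on the analytic gradients.

    Parameters
    ----------
    features, labels : per-mouse lists (or single arrays) of window feature
        matrices and integer state labels; UNKNOWN windows are dropped
    config : optimizer settings
    mu : reconstruction weight (defaults to the middle of the config grid)
    val_features, val_labels : optional validation mice for early stopping on
        validation balanced accuracy (patience ``config.patience``)
    """
    if isinstance(features, np.ndarray):
        features, labels = [features], [labels]
    X, y = _stack_labeled(features, labels)
    counts = np.bincount(y, minlength=N_STATES)
    if (counts == 0).any():
        missing = [STATE_NAMES[i] for i in range(N_STATES) if counts[i] == 0]
        raise ValueError(
            f"training labels missing state(s) {missing}; counts per state "
            f"{dict(zip(STATE_NAMES, counts.tolist()))}"
        )
    if mu is None:
        mu = config.mu_grid[min(1, len(config.mu_grid) - 1)]
    d = X.shape[1]
    rng = np.random.default_rng(config.seed)
    params = {
        "A": rng.normal(0.0, 0.01, size=(LATENT_DIM, d)),
        "b": np.zeros(LATENT_DIM),
        "c_diag": np.ones(N_STATES),
        "H": np.clip(rng.normal(0.0, 0.01, size=(LATENT_DIM, d)), 0.0, None),
    }
    Y = _one_hot(y)
    have_val = val_features is not None
    if have_val:
        if isinstance(val_features, np.ndarray):
            val_features, val_labels = [val_features], [val_labels]
        Xv, yv = _stack_labeled(val_features, val_labels)

    # Adam state
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(vv) for k, vv in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    step = 0
    n = X.shape[0]
    loss_trace: list[float] = []
    best_val, best_params, since_best = -np.inf, None, 0

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            total, _p, _r, grads = _loss_and_grads(params, X[idx], Y[idx], mu)
            epoch_loss += total * len(idx)
            step += 1
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1 ** step)
                vhat = v[k] / (1 - beta2 ** step)
                params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + eps)
            params["H"] = np.clip(params["H"], 0.0, None)   # projection
        loss_trace.append(epoch_loss / n)
        if have_val:
            model = ElectomeModel(
                params["A"].copy(), params["b"].copy(),
                params["c_diag"].copy(), params["H"].copy(), mu, seed=config.seed,
            )
            pv = _softmax(model.logits(Xv)).argmax(axis=1)
            ba = balanced_accuracy(yv, pv)
            if ba > best_val + 1e-9:
                best_val, best_params, since_best = ba, {k: p.copy() for k, p in params.items()}, 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if have_val and best_params is not None:
        params = best_params
    model = ElectomeModel(
        params["A"], params["b"], params["c_diag"], params["H"], mu, seed=config.seed,
    )
    model.loss_trace = np.array(loss_trace)
    return model


def predict(
    model: ElectomeModel,
    features,
    valid_mask: np.ndarray | None = None,
    window_s: float = 2.0,
) -> Hypnogram:
    """Per-window state probabilities softmax(C(Ax+b)) and argmax labels.

    Ties break in state order (wake < NREM < REM).  Invalid windows get
    UNKNOWN labels and NaN probabilities.
    """
    if isinstance(features, FeatureTensor):
        from .features import flatten

        if valid_mask is None:
            valid_mask = features.valid_mask
        window_s = features.window_s
        features = flatten(features)
    X = np.asarray(features, dtype=float)
    if X.shape[1] != model.d:
        raise ValueError(f"feature dimension {X.shape[1]} != model d={model.d}")
    P = _softmax(model.logits(X))
    labels = P.argmax(axis=1)       # argmax takes the first maximum: state order
    if valid_mask is not None:
        valid_mask = np.asarray(valid_mask, dtype=bool)
        labels = np.where(valid_mask, labels, UNKNOWN)
        P = P.copy()
        P[~valid_mask] = np.nan
    return Hypnogram(labels=labels, window_s=window_s, probabilities=P)


def balanced_accuracy(truth, predicted) -> float:
    """Mean per-state recall, in percent.

    UNKNOWN truth windows are excluded.  States absent from the truth are
    dropped (with a warning) and the average runs over the present states,
    weighting each state equally regardless of time spent in it.
    """
    t = truth.labels if isinstance(truth, Hypnogram) else np.asarray(truth, dtype=np.int64)
    p = predicted.labels if isinstance(predicted, Hypnogram) else np.asarray(predicted, dtype=np.int64)
    if len(t) != len(p):
        raise ValueError("truth and prediction lengths differ")
    keep = t != UNKNOWN
    t, p = t[keep], p[keep]
    recalls = []
    for s in STATES:
        n_s = (t == s).sum()
        if n_s == 0:
            warnings.warn(f"state {state_name(s)} absent from truth; dropped from balanced accuracy")
            continue
        recalls.append(((t == s) & (p == s)).sum() / n_s)
    if not recalls:
        raise ValueError("no labeled truth windows")
    return 100.0 * float(np.mean(recalls))


@dataclass
class CVResult:
    """Nested cross-validation outcome."""

    outer_balanced_accuracy: list[float]
    outer_state_recalls: list[dict[str, float]]
    chosen_mu: float
    final_model: ElectomeModel
    inner_scores: dict[float, float] = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)


def _per_state_recalls(t: np.ndarray, p: np.ndarray) -> dict[str, float]:
    keep = t != UNKNOWN
    t, p = t[keep], p[keep]
    out = {}
    for s, nm in zip(STATES, STATE_NAMES):
        n_s = (t == s).sum()
        out[nm] = float(((t == s) & (p == s)).sum() / n_s) if n_s else float("nan")
    return out


def nested_cv(features, labels, config: TrainingConfig) -> CVResult:
    """Leave-one-mouse-out nested cross-validation over the mu grid.

    Outer loop: each mouse in turn is the test mouse.  Inner loop:
    ``config.n_inner_splits`` shuffled splits of the remaining mice into
    train/validation (6/2 when 8 remain, otherwise one validation mouse)
    score each mu by mean validation balanced accuracy.  The best mu is refit
    on all outer-training mice and scored on the test mouse; finally the mu
    winning most often is refit on ALL mice to give the final model.
    """
    M = len(features)
    if M < 4:
        raise ValueError(
            f"nested CV needs >= 4 mice (got {M}): inner split requires >= 3 train + 1 validation"
        )
    n_val = 2 if M - 1 >= 8 else 1
    rng = np.random.default_rng(config.seed)
    outer_ba: list[float] = []
    outer_recalls: list[dict[str, float]] = []
    mu_wins: dict[float, int] = {mu: 0 for mu in config.mu_grid}
    inner_means: dict[float, list[float]] = {mu: [] for mu in config.mu_grid}

    for test_i in range(M):
        rest = [i for i in range(M) if i != test_i]
        mu_scores = {mu: [] for mu in config.mu_grid}
        for split in range(config.n_inner_splits):
            perm = rng.permutation(rest)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            for mu in config.mu_grid:
                model = fit(
                    [features[i] for i in tr_idx], [labels[i] for i in tr_idx],
                    config, mu=mu,
                    val_features=[features[i] for i in val_idx],
                    val_labels=[labels[i] for i in val_idx],
                )
                Xv, yv = _stack_labeled(
                    [features[i] for i in val_idx], [labels[i] for i in val_idx]
                )
                pv = predict(model, Xv).labels
                mu_scores[mu].append(balanced_accuracy(yv, pv))
        mean_scores = {mu: float(np.mean(v)) for mu, v in mu_scores.items()}
        for mu in config.mu_grid:
            inner_means[mu].append(mean_scores[mu])
        best_mu = max(config.mu_grid, key=lambda mu: mean_scores[mu])
        mu_wins[best_mu] += 1
        model = fit(
            [features[i] for i in rest], [labels[i] for i in rest], config, mu=best_mu
        )
        Xt, yt = _stack_labeled([features[test_i]], [labels[test_i]])
        pt = predict(model, Xt).labels
        outer_ba.append(balanced_accuracy(yt, pt))
        outer_recalls.append(_per_state_recalls(yt, pt))

    chosen_mu = max(config.mu_grid, key=lambda mu: (mu_wins[mu], np.mean(inner_means[mu])))
    final_model = fit(list(features), list(labels), config, mu=chosen_mu)
    return CVResult(
        outer_balanced_accuracy=outer_ba,
        outer_state_recalls=outer_recalls,
        chosen_mu=chosen_mu,
        final_model=final_model,
        inner_scores={mu: float(np.mean(v)) for mu, v in inner_means.items()},
        geometry={
            "n_outer_folds": M,
            "n_inner_splits": config.n_inner_splits,
            "n_inner_validation": n_val,
            "n_inner_train": M - 1 - n_val,
        },
    )


def extract_single_region_power(tensor: FeatureTensor, region: str) -> np.ndarray:
    """One region's diagonal power features per window: (n_windows, F)."""
    try:
        i = tensor.regions.index(region)
    except ValueError:
        raise ValueError(f"region {region!r} not in tensor regions {tensor.regions}") from None
    return tensor.values[:, i, i, :]


def single_region_model(
    features, labels, config: TrainingConfig, mu: float | None = None, **kw
) -> ElectomeModel:
    """Train the same architecture on one region's 29 power features (d=29)."""
    feats = [features] if isinstance(features, np.ndarray) else list(features)
    for X in feats:
        if np.asarray(X).shape[1] != feats[0].shape[1]:
            raise ValueError("inconsistent single-region feature dimensions")
    return fit(features, labels, config, mu=mu, **kw)


def electome_factors(model: ElectomeModel, n_regions: int | None = None,
                     n_freqs: int | None = None) -> dict:
    """Unflatten H's rows to regions x regions x frequency factor tensors.

    Rows 0-2 are the supervised factors (tagged wake/nrem/rem); the remaining
    29 rows are unsupervised.  All entries are non-negative by the training
    projection.
    """
    if n_regions is None:
        n_regions = len(model.regions) if model.regions else int(round(np.sqrt(model.d / 29)))
    if n_freqs is None:
        n_freqs = model.d // n_regions ** 2
    if n_regions ** 2 * n_freqs != model.d:
        raise ValueError("model d inconsistent with regions x regions x freqs")
    tensors = model.H.reshape(LATENT_DIM, n_regions, n_regions, n_freqs)
    return {
        "supervised": {nm: tensors[i] for i, nm in enumerate(STATE_NAMES)},
        "unsupervised": tensors[N_SUPERVISED:],
    }
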
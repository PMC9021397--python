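"""PLS-DA fingerprint classifier.

Partial least squares discriminant analysis (NIPALS, one response) with
leave-one-out cross-validation, a balanced-resampling voting ensemble
with a gray-zone majority vote, and VIP variable importance.

The two classes are coded y = +1 (deceased) / -1 (survivor); the decision
threshold on the continuous PLS prediction is 0.  X is mean-centered only
(no unit-variance scaling), preserving the intensity weighting of the
spectral bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SURVIVOR",
    "DECEASED",
    "PLSModel",
    "PLSDiscriminator",
    "ConfusionMetrics",
    "EnsembleVote",
    "VoteEnsemble",
    "EnsembleResults",
    "fit_pls",
    "plsda_predict",
    "loocv",
    "vip_scores",
    "balanced_ensemble",
    "majority_vote",
    "confusion_metrics",
]

SURVIVOR = "survivor"
DECEASED = "deceased"


def encode_labels(labels) -> np.ndarray:
    """Map {survivor, deceased} labels (or +-1 codes) to a +-1 float vector."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        bad = set(np.unique(arr)) - {SURVIVOR, DECEASED}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        return np.where(arr == DECEASED, 1.0, -1.0)
    y = arr.astype(float)
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("numeric class codes must be -1 or +1")
    return y


def decode_labels(y: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(y) > 0, DECEASED, SURVIVOR)


@dataclass
class PLSModel:
    """Fitted PLS1 model (sequential NIPALS deflation).

    ``x_weights`` columns are unit-norm deflated-X weights; ``x_loadings``
    and ``y_loadings`` the corresponding loadings; ``coefficients`` the
    equivalent single regression vector on centered X.
    """

    n_components: int
    x_weights: np.ndarray     # (p, A)
    x_loadings: np.ndarray    # (p, A)
    y_loadings: np.ndarray    # (A,)
    x_scores: np.ndarray      # (n, A)
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray  # (p,)

    @property
    def coefficient_vector(self) -> np.ndarray:
        return self.coefficients

    def predict_score(self, X_new: np.ndarray) -> np.ndarray:
        """Continuous PLS prediction for new rows."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.x_mean.size:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model was trained on "
                f"{self.x_mean.size}")
        return (X_new - self.x_mean) @ self.coefficients + self.y_mean

    def predict_label(self, X_new: np.ndarray) -> np.ndarray:
        return decode_labels(self.predict_score(X_new))


def fit_pls(X, y, n_components: int = 7) -> PLSModel:
    """Fit a PLS1 model by NIPALS with sequential deflation of X and y.

    ``y`` may be string class labels or a +-1 code vector; both classes
    must be present.  X and y are mean-centered (centering stored on the
    model); the fit is deterministic given the input row order.
    """
    X = np.asarray(X, dtype=float)
    yv = encode_labels(y)
    if X.ndim != 2 or X.shape[0] != yv.size:
        raise ValueError("X must be 2-D with one row per y entry")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if np.unique(yv).size < 2:
        raise ValueError("both classes must be present in y")
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds rank bound "
            f"min(n-1, p)={min(n - 1, p)}")
    x_mean = X.mean(axis=0)
    y_mean = float(yv.mean())
    Xa = X - x_mean
    ya = yv - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = Xa.T @ ya
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise ValueError(
                f"PLS deflation exhausted at component {a + 1}: residual "
                "covariance is zero")
        w /= nw
        t = Xa @ w
        tt = t @ t
        if tt < 1e-14:
            raise ValueError(f"degenerate score vector at component {a + 1}")
        pvec = Xa.T @ t / tt
        q = ya @ t / tt
        Xa = Xa - np.outer(t, pvec)
        ya = ya - q * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, pvec, q, t

    coef = W @ np.linalg.solve(P.T @ W, Q)
    return PLSModel(n_components=n_components, x_weights=W, x_loadings=P,
                    y_loadings=Q, x_scores=T, x_mean=x_mean, y_mean=y_mean,
                    coefficients=coef)


def plsda_predict(model: PLSModel, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores and class labels for new samples."""
    scores = model.predict_score(X_new)
    return scores, decode_labels(scores)


def vip_scores(model: PLSModel, threshold: float = 1.0
               ) -> tuple[np.ndarray, np.ndarray]:
    """Variable importance in projection for each X column.

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ) with SS_a the
    y-variance explained by component a (q_a^2 t_a't_a) and w the
    unit-norm component weights.  The mean of squared VIPs is exactly 1;
    variables with VIP above ``threshold`` (default 1) form the selected
    set.
    """
    p = model.x_weights.shape[0]
    ss = model.y_loadings**2 * np.einsum("na,na->a", model.x_scores,
                                         model.x_scores)
    total = ss.sum()
    if total <= 0:
        raise ValueError("model explains zero y-variance; VIP undefined")
    vip = np.sqrt(p * (model.x_weights**2 @ ss) / total)
    return vip, vip > threshold


@dataclass(frozen=True)
class ConfusionMetrics:
    """Binary confusion counts and the derived standard fractions."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity, "accuracy": self.accuracy}


def confusion_metrics(predicted, truth, positive_class: str = DECEASED
                      ) -> ConfusionMetrics:
    """Confusion counts plus sensitivity/specificity/accuracy.

    ``positive_class`` (default deceased) defines the positive label.
    """
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    pp = pred == positive_class
    tp_ = true == positive_class
    return ConfusionMetrics(tp=int(np.sum(pp & tp_)),
                            fp=int(np.sum(pp & ~tp_)),
                            tn=int(np.sum(~pp & ~tp_)),
                            fn=int(np.sum(~pp & tp_)))


def loocv(X, y, n_components: int = 7
          ) -> tuple[np.ndarray, ConfusionMetrics]:
    """Leave-one-out cross-validation of the PLS-DA classifier.

    Fits n models, each excluding one sample, and records the held-out
    label; metrics are computed on held-out predictions only.
    """
    X = np.asarray(X, dtype=float)
    yv = encode_labels(y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    counts = {c: int(np.sum(yv == c)) for c in (-1.0, 1.0)}
    if min(counts.values()) < 2:
        raise ValueError(
            "each class needs >= 2 members so no LOOCV fold loses a class")
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit_pls(X[mask], yv[mask], n_components)
        preds[i] = model.predict_score(X[i])[0]
        mask[i] = True
    labels = decode_labels(preds)
    return labels, confusion_metrics(labels, decode_labels(yv))


@dataclass(frozen=True)
class EnsembleVote:
    """Per-sample majority-vote outcome over ensemble iterations."""

    sample_id: str
    votes_deceased: int
    votes_total: int
    vote_share: float
    predicted_class: str
    margin: float
    gray_zone: bool


def majority_vote(votes_deceased: int, votes_total: int,
                  gray_threshold: float = 0.10,
                  sample_id: str = "") -> EnsembleVote:
    """Majority vote with a gray zone for small margins.

    The margin is |vote_share - 0.5|; a sample is gray-zone iff its margin
    is strictly below ``gray_threshold``.  An exact 50/50 tie defaults to
    the lower-risk survivor class and is always flagged gray.
    """
    if votes_total <= 0:
        raise ValueError("votes_total must be positive")
    if not 0 <= votes_deceased <= votes_total:
        raise ValueError("votes_deceased out of range")
    share = votes_deceased / votes_total
    # integer margin arithmetic avoids float-boundary artifacts at the cut
    margin_num = abs(2 * votes_deceased - votes_total)
    margin = margin_num / (2 * votes_total)
    gray = margin_num < 2.0 * gray_threshold * votes_total - 1e-9
    if 2 * votes_deceased == votes_total:
        pred, gray = SURVIVOR, True
    else:
        pred = DECEASED if 2 * votes_deceased > votes_total else SURVIVOR
    return EnsembleVote(sample_id=sample_id, votes_deceased=votes_deceased,
                        votes_total=votes_total, vote_share=share,
                        predicted_class=pred, margin=margin, gray_zone=gray)


@dataclass
class EnsembleResults:
    """Results of the balanced-resampling PLS-DA voting ensemble."""

    votes: pd.DataFrame                 # per-sample vote table
    iteration_metrics: pd.DataFrame     # per-iteration LOOCV metrics
    truth: np.ndarray
    gray_threshold: float
    n_iter: int
    per_class: int
    n_components: int
    seed: int

    @property
    def predicted_class(self) -> np.ndarray:
        return self.votes["predicted_class"].to_numpy()

    @property
    def gray_zone(self) -> np.ndarray:
        return self.votes["gray_zone"].to_numpy()

    def metrics(self, exclude_gray: bool = False) -> ConfusionMetrics:
        """Majority-vote confusion metrics against the true classes."""
        keep = ~self.gray_zone if exclude_gray else np.ones(len(self.votes),
                                                            dtype=bool)
        return confusion_metrics(self.predicted_class[keep], self.truth[keep])

    def summary(self) -> str:
        m = self.metrics()
        lines = [
            "Balanced PLS-DA voting ensemble",
            f"  iterations: {self.n_iter}, per-class draw: {self.per_class}, "
            f"components: {self.n_components}, seed: {self.seed}",
            f"  samples: {len(self.votes)}  gray-zone "
            f"(margin < {self.gray_threshold:.0%}): {int(self.gray_zone.sum())}",
            f"  majority-vote accuracy:    {m.accuracy:.3f}",
            f"  majority-vote sensitivity: {m.sensitivity:.3f}",
            f"  majority-vote specificity: {m.specificity:.3f}",
            f"  mean per-iteration LOOCV accuracy: "
            f"{self.iteration_metrics['accuracy'].mean():.3f}",
        ]
        return "\n".join(lines)


class VoteEnsemble:
    """Balanced-resampling PLS-DA ensemble with majority-vote classification.

    Repeatedly draws ``per_class`` samples per class without replacement,
    fits a PLS-DA model to each balanced subsample and cross-validates it
    by LOOCV.  Per iteration, in-subsample members are voted by their
    held-out LOOCV prediction and out-of-subsample members by the fitted
    model's prediction, so every sample accrues exactly ``n_iter`` votes.

    Randomness is counter-based: iteration ``k`` derives its RNG from
    ``(seed, k)``, so growing ``n_iter`` never reshuffles earlier draws.
    """

    def __init__(self, X, y, sample_ids=None, n_components: int = 7,
                 n_iter: int = 100, per_class: int = 25,
                 gray_threshold: float = 0.10):
        self.X = np.asarray(X, dtype=float)
        self.y = encode_labels(y)
        n = self.X.shape[0]
        if sample_ids is None:
            sample_ids = [f"S{i:03d}" for i in range(n)]
        self.sample_ids = list(sample_ids)
        self.n_components = n_components
        self.n_iter = n_iter
        self.per_class = per_class
        self.gray_threshold = gray_threshold
        for cls in (-1.0, 1.0):
            avail = int(np.sum(self.y == cls))
            if avail < per_class:
                name = DECEASED if cls > 0 else SURVIVOR
                raise ValueError(
                    f"per_class={per_class} exceeds the {name} class size "
                    f"({avail}); reduce per_class to at most {avail}")

    def fit(self, seed: int = 0) -> EnsembleResults:
        n = self.X.shape[0]
        idx_surv = np.flatnonzero(self.y < 0)
        idx_dec = np.flatnonzero(self.y > 0)
        votes_dec = np.zeros(n, dtype=int)
        iter_rows = []
        for it in range(self.n_iter):
            rng = np.random.default_rng([seed, it])
            sub = np.concatenate([
                rng.choice(idx_surv, size=self.per_class, replace=False),
                rng.choice(idx_dec, size=self.per_class, replace=False)])
            in_sub = np.zeros(n, dtype=bool)
            in_sub[sub] = True
            cv_labels, cv_metrics = loocv(self.X[sub], self.y[sub],
                                          self.n_components)
            votes_dec[sub] += (cv_labels == DECEASED).astype(int)
            model = fit_pls(self.X[sub], self.y[sub], self.n_components)
            out = np.flatnonzero(~in_sub)
            if out.size:
                out_labels = model.predict_label(self.X[out])
                votes_dec[out] += (out_labels == DECEASED).astype(int)
            iter_rows.append({"iteration": it,
                              "accuracy": cv_metrics.accuracy,
                              "sensitivity": cv_metrics.sensitivity,
                              "specificity": cv_metrics.specificity})
        rows = [majority_vote(int(votes_dec[i]), self.n_iter,
                              self.gray_threshold, self.sample_ids[i])
                for i in range(n)]
        votes = pd.DataFrame([vars(r) for r in rows])
        return EnsembleResults(votes=votes,
                               iteration_metrics=pd.DataFrame(iter_rows),
                               truth=decode_labels(self.y),
                               gray_threshold=self.gray_threshold,
                               n_iter=self.n_iter, per_class=self.per_class,
                               n_components=self.n_components, seed=seed)


class PLSDiscriminator:
    """Thin model wrapper: ``PLSDiscriminator(X, y).fit()`` -> :class:`PLSModel`."""

    def __init__(self, X, y, n_components: int = 7):
        self.X = np.asarray(X, dtype=float)
        self.y = y
        self.n_components = n_components

    def fit(self) -> PLSModel:
        return fit_pls(self.X, self.y, self.n_components)


def balanced_ensemble(X, y, n_iter: int = 100, per_class: int = 25,
                      n_components: int = 7, seed: int = 0,
                      gray_threshold: float = 0.10,
                      sample_ids=None) -> EnsembleResults:
    """Functional front door to :class:`VoteEnsemble`."""
    return VoteEnsemble(X, y, sample_ids=sample_ids, n_components=n_components,
                        n_iter=n_iter, per_class=per_class,
                        gray_threshold=gray_threshold).fit(seed=seed)
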
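"""Multinomial logistic regression fitted by maximum likelihood.

The model maps a feature vector x to three class probabilities through a
softmax over linear scores, with the last class (24-lbs) as the implicit
reference (zero coefficients).  Fitting is a deterministic damped Newton
iteration from a zero start with a small ridge penalty (intercepts excluded)
to stabilize quasi-separated training splits; if the coefficient norm
diverges (perfect separation), the fit restarts with a stronger ridge and
flags it.  Identical inputs and options yield bit-identical coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLROptions", "MLRModel", "fit", "predict_proba", "predict_label"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MLROptions:
    max_iter: int = 500
    tol: float = 1e-8
    ridge: float = 1e-6
    separation_threshold: float = 50.0   # coefficient ∞-norm triggering fallback
    separation_ridge: float = 1e-3


@dataclass
class MLRModel:
    classes: tuple[str, ...]
    coef: np.ndarray                     # (n_classes-1, n_features+1), col 0 = intercept
    converged: bool = True
    n_iter: int = 0
    log_likelihood: float = np.nan
    separation_fallback: bool = False
    subjects: frozenset = field(default_factory=frozenset)  # provenance tag

    @property
    def n_features(self) -> int:
        return self.coef.shape[1] - 1

    def save(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "classes": list(self.classes),
                    "coef": [[float(v) for v in row] for row in self.coef],
                    "converged": self.converged,
                    "n_iter": self.n_iter,
                    "log_likelihood": float(self.log_likelihood),
                    "separation_fallback": self.separation_fallback,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path) -> "MLRModel":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(
            classes=tuple(d["classes"]),
            coef=np.array(d["coef"], dtype=float),
            converged=d["converged"],
            n_iter=d["n_iter"],
            log_likelihood=d["log_likelihood"],
            separation_fallback=d["separation_fallback"],
        )


def _probs(Xd: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Class probabilities, reference class last; numerically stable softmax."""
    scores = Xd @ B.T                                  # (n, K-1)
    full = np.concatenate([scores, np.zeros((scores.shape[0], 1))], axis=1)
    full -= full.max(axis=1, keepdims=True)
    np.exp(full, out=full)
    full /= full.sum(axis=1, keepdims=True)
    return full


def _nll(P: np.ndarray, Yidx: np.ndarray, B: np.ndarray, ridge: float) -> float:
    eps = 1e-300
    ll = np.log(P[np.arange(P.shape[0]), Yidx] + eps).sum()
    pen = 0.5 * ridge * float((B[:, 1:] ** 2).sum())
    return -ll + pen


def _newton_fit(
    Xd: np.ndarray,
    Yidx: np.ndarray,
    K: int,
    opts: MLROptions,
    ridge: float,
    guard: float | None = None,
) -> tuple[np.ndarray, bool, int, bool]:
    n, p = Xd.shape
    Km1 = K - 1
    B = np.zeros((Km1, p))
    Y1 = np.zeros((n, Km1))
    for k in range(Km1):
        Y1[Yidx == k, k] = 1.0
    pen_mask = np.ones(p)
    pen_mask[0] = 0.0  # intercept unpenalized
    eye = np.eye(Km1)
    guard = opts.separation_threshold if guard is None else guard
    converged = False
    separated = False
    f = _nll(_probs(Xd, B), Yidx, B, ridge)
    it = 0
    for it in range(1, opts.max_iter + 1):
        P = _probs(Xd, B)
        Pk = P[:, :Km1]
        G = (Pk - Y1).T @ Xd + ridge * B * pen_mask          # (Km1, p)
        gmax = np.abs(G).max()
        if gmax < opts.tol * max(1.0, n):
            converged = True
            break
        # Hessian: H[(a,i),(b,j)] = sum_n Pk[n,a] (δ_ab − Pk[n,b]) x_ni x_nj
        W = Pk[:, :, None] * (eye[None, :, :] - Pk[:, None, :])  # (n, Km1, Km1)
        H = np.einsum("nab,ni,nj->aibj", W, Xd, Xd, optimize=True)
        H = H.reshape(Km1 * p, Km1 * p)
        H[np.arange(Km1 * p), np.arange(Km1 * p)] += ridge * np.tile(pen_mask, Km1) + 1e-10
        try:
            delta = np.linalg.solve(H, G.reshape(-1)).reshape(Km1, p)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, G.reshape(-1), rcond=None)[0].reshape(Km1, p)
        step = 1.0
        for _ in range(30):
            Bn = B - step * delta
            fn = _nll(_probs(Xd, Bn), Yidx, Bn, ridge)
            if fn <= f:
                break
            step *= 0.5
        else:
            converged = gmax < 1e-4 * max(1.0, n)
            break
        B, f = Bn, fn
        if np.abs(B).max() > guard:
            separated = True
            break
    return B, converged, it, separated


def _scores_nll_batch(
    Xd: np.ndarray, Y1: np.ndarray, B: np.ndarray, ridge: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(scores (b,n,K-1), penalized NLL (b,)) for a coefficient stack."""
    scores = Xd @ np.swapaxes(B, 1, 2)
    m = np.maximum(scores.max(axis=2), 0.0)                 # reference score is 0
    lse = m + np.log(np.exp(-m) + np.exp(scores - m[..., None]).sum(axis=2))
    picked = (scores * Y1).sum(axis=2)                      # 0 for the reference class
    ll = (picked - lse).sum(axis=1)
    pen = 0.5 * ridge * (B[:, :, 1:] ** 2).sum(axis=(1, 2))
    return scores, -ll + pen


def _newton_fit_batch(
    Xd: np.ndarray,
    Yidx: np.ndarray,
    K: int,
    opts: MLROptions,
    ridge: np.ndarray,
    guard: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Damped Newton on a stack of same-shaped problems.

    ``Xd``: (b, n, p) with intercept column prepended; ``ridge``: (b,).
    Returns (coefficients (b, K-1, p), converged mask, separated mask).
    """
    b, n, p = Xd.shape
    Km1 = K - 1
    q = Km1 * p
    B = np.zeros((b, Km1, p))
    Y1 = np.zeros((b, n, Km1))
    for k in range(Km1):
        Y1[..., k] = Yidx == k
    pen = np.ones(p)
    pen[0] = 0.0
    diag_idx = np.arange(q)
    pen_q = np.tile(pen, Km1)
    guard = opts.separation_threshold if guard is None else guard
    converged = np.zeros(b, dtype=bool)
    separated = np.zeros(b, dtype=bool)
    scores, f = _scores_nll_batch(Xd, Y1, B, ridge)
    H = np.empty((b, q, q))
    for _ in range(opts.max_iter):
        # softmax probabilities of the non-reference classes from scores
        m = np.maximum(scores.max(axis=2, keepdims=True), 0.0)
        E = np.exp(scores - m)
        denom = np.exp(-m[..., 0]) + E.sum(axis=2)
        Pk = E / denom[..., None]                            # (b, n, Km1)
        G = np.swapaxes(Pk - Y1, 1, 2) @ Xd + ridge[:, None, None] * B * pen
        gmax = np.abs(G).max(axis=(1, 2))
        converged |= gmax < opts.tol * max(1.0, n)
        active = ~(converged | separated)
        if not active.any():
            break
        # Hessian blocks H[u,v] = X^T diag(P_u (δ_uv − P_v)) X, filled per pair
        XdT = np.swapaxes(Xd, 1, 2)
        for u in range(Km1):
            for v in range(u, Km1):
                w = Pk[..., u] * ((1.0 if u == v else 0.0) - Pk[..., v])
                blk = XdT @ (Xd * w[..., None])
                H[:, u * p : (u + 1) * p, v * p : (v + 1) * p] = blk
                if v != u:
                    H[:, v * p : (v + 1) * p, u * p : (u + 1) * p] = blk
        H[:, diag_idx, diag_idx] += ridge[:, None] * pen_q + 1e-10
        delta = np.linalg.solve(H, G.reshape(b, q, 1)).reshape(b, Km1, p)
        delta[~active] = 0.0
        step = np.ones(b)
        Bn = B - delta
        scores_n, fn = _scores_nll_batch(Xd, Y1, Bn, ridge)
        for _ in range(30):
            bad = active & (fn > f)
            if not bad.any():
                break
            step[bad] *= 0.5
            Bn[bad] = B[bad] - step[bad, None, None] * delta[bad]
            scores_n[bad], fn[bad] = _scores_nll_batch(Xd[bad], Y1[bad], Bn[bad], ridge[bad])
        else:
            converged |= active & (gmax < 1e-4 * max(1.0, n))
            break
        B, f, scores = Bn, fn, scores_n
        separated |= active & (np.abs(B).max(axis=(1, 2)) > guard)
    return B, converged, separated


def fit_batch(
    X: np.ndarray,
    y: np.ndarray,
    classes: tuple[str, ...],
    options: MLROptions | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a stack of same-shaped problems; used by the evaluation loop.

    ``X``: (b, n, d) feature stacks, ``y``: (b, n) integer class indices.
    Applies the same separation fallback as :func:`fit` (flagged problems
    are refitted with the stronger ridge).  Returns the coefficient stack
    (b, n_classes−1, d+1) and the separation-fallback mask.
    """
    opts = options or MLROptions()
    X = np.asarray(X, dtype=float)
    Yidx = np.asarray(y, dtype=int)
    b, n, _ = X.shape
    K = len(classes)
    Xd = np.concatenate([np.ones((b, n, 1)), X], axis=2)
    ridge = np.full(b, opts.ridge)
    B, converged, separated = _newton_fit_batch(Xd, Yidx, K, opts, ridge)
    if separated.any() and opts.separation_ridge > opts.ridge:
        idx = np.flatnonzero(separated)
        Bs, _, _ = _newton_fit_batch(
            Xd[idx], Yidx[idx], K, opts,
            np.full(idx.size, opts.separation_ridge), guard=np.inf,
        )
        B[idx] = Bs
    return B, separated


def predict_proba_batch(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Probabilities for a coefficient stack: (b, n, n_classes)."""
    X = np.asarray(X, dtype=float)
    Xd = np.concatenate([np.ones((*X.shape[:2], 1)), X], axis=2)
    scores = Xd @ np.swapaxes(coef, 1, 2)
    full = np.concatenate([scores, np.zeros((*scores.shape[:2], 1))], axis=2)
    full -= full.max(axis=2, keepdims=True)
    np.exp(full, out=full)
    full /= full.sum(axis=2, keepdims=True)
    return full


def fit(
    X: np.ndarray,
    y: np.ndarray,
    classes: tuple[str, ...],
    options: MLROptions | None = None,
    subjects=None,
) -> MLRModel:
    """Fit by maximum likelihood (deterministic damped Newton, zero init).

    ``y`` holds class labels (or integer indices into ``classes``); every
    class must be represented.  On detected separation the fit restarts with
    ``separation_ridge`` and the returned model is flagged.
    """
    opts = options or MLROptions()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if y.dtype.kind in "iu":
        Yidx = y.astype(int)
    else:
        lut = {c: k for k, c in enumerate(classes)}
        try:
            Yidx = np.array([lut[v] for v in y])
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in classes {classes}") from exc
    K = len(classes)
    present = np.unique(Yidx)
    if present.size < K:
        missing = [classes[k] for k in range(K) if k not in present]
        raise ValueError(f"class(es) {missing} absent from training labels")
    Xd = np.concatenate([np.ones((X.shape[0], 1)), X], axis=1)

    B, converged, it, separated = _newton_fit(Xd, Yidx, K, opts, opts.ridge)
    fallback = False
    if separated and opts.separation_ridge > opts.ridge:
        log.warning(
            "separation detected (|coef| > %g); refitting with ridge %g",
            opts.separation_threshold, opts.separation_ridge,
        )
        B, converged, it, _ = _newton_fit(Xd, Yidx, K, opts, opts.separation_ridge, guard=np.inf)
        fallback = True
    if not converged:
        warnings.warn(
            f"MLR fit did not converge in {opts.max_iter} iterations", RuntimeWarning
        )
    P = _probs(Xd, B)
    ll = float(np.log(P[np.arange(P.shape[0]), Yidx] + 1e-300).sum())
    return MLRModel(
        classes=tuple(classes),
        coef=B,
        converged=converged,
        n_iter=it,
        log_likelihood=ll,
        separation_fallback=fallback,
        subjects=frozenset(subjects or ()),
    )


def predict_proba(model: MLRModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities ``(n, n_classes)`` in the model's class order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature arity {X.shape[1]} != model arity {model.n_features}"
        )
    Xd = np.concatenate([np.ones((X.shape[0], 1)), X], axis=1)
    return _probs(Xd, model.coef)


def predict_label(model: MLRModel, X: np.ndarray) -> np.ndarray:
    """Argmax class per row; exact ties resolve to the earlier class."""
    P = predict_proba(model, X)
    return np.asarray(model.classes, dtype=object)[P.argmax(axis=1)]
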
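"""Shapley-value feature attribution for the classifier families.

Two exact routes are provided and one generic estimator:

* :func:`linear_shap` — closed-form interventional Shapley values for linear
  decision functions: ``phi_j = w_j * (x_j - mean(background_j))`` per
  output margin;
* tree models (LightGBM) use the booster's path-dependent TreeSHAP
  (``pred_contrib``);
* :func:`sampling_shap` — a model-agnostic permutation-sampling estimator.
  Each sampled permutation telescopes to ``f(x) - E[f(background)]``, so the
  estimate is exactly additive per sample regardless of the number of
  permutations; it serves as an independent cross-check of the exact routes.
"""

from __future__ import annotations

import numpy as np


def linear_shap(coef: np.ndarray, X: np.ndarray,
                background: np.ndarray) -> np.ndarray:
    """Shapley values of a linear margin ``f_c(x) = w_c . x + b_c``.

    Returns an array of shape (n_outputs, n_samples, n_features).
    """
    coef = np.atleast_2d(np.asarray(coef, dtype=float))
    X = np.asarray(X, dtype=float)
    mu = np.asarray(background, dtype=float).mean(axis=0)
    return coef[:, None, :] * (X - mu)[None, :, :]


def sampling_shap(predict: "callable", X: np.ndarray, background: np.ndarray,
                  n_permutations: int = 20,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Permutation-sampling Shapley values of ``predict`` (which maps an
    (n, p) array to an (n,) or (n, k) array of outputs).

    Returns (n_outputs, n_samples, n_features).  Exactly additive:
    ``phi.sum(axis=-1) == predict(X) - predict(background).mean(axis=0)``.
    """
    rng = rng or np.random.default_rng(0)
    X = np.asarray(X, dtype=float)
    bg = np.asarray(background, dtype=float)
    n, p = X.shape
    m = bg.shape[0]

    def pred(mat: np.ndarray) -> np.ndarray:
        out = np.asarray(predict(mat), dtype=float)
        return out[:, None] if out.ndim == 1 else out

    k = pred(X[:1]).shape[1]
    phi = np.zeros((k, n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        # z: for each sample, every background row progressively overwritten
        z = np.tile(bg, (n, 1))                     # (n*m, p)
        prev = pred(z).reshape(n, m, k).mean(axis=1)
        for j in order:
            z[:, j] = np.repeat(X[:, j], m)
            cur = pred(z).reshape(n, m, k).mean(axis=1)
            phi[:, :, j] += (cur - prev).T
            prev = cur
    return phi / n_permutations


def mean_abs_importance(phi: np.ndarray) -> np.ndarray:
    """Per-feature importance: mean |Shapley value| over samples and outputs."""
    return np.abs(phi).mean(axis=(0, 1))
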
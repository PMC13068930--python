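"""Shapley-value estimation for tabular regressors.

Two routes:

* ``linear_shapley`` — the closed form for a linear model: with respect to a
  background distribution, the Shapley value of feature j for sample i is
  ``coef_j * (x_ij - background_mean_j)``, exactly.
* ``permutation_shapley`` — Monte-Carlo estimation for arbitrary models by
  sampling feature orderings.  For each ordering, features are switched one
  at a time from background values to the sample's values and the marginal
  change in the background-averaged prediction is credited to the switched
  feature.  Because the marginal contributions along one ordering telescope
  to ``f(x) - base``, the *local-accuracy identity*
  ``base + sum_j phi_ij = f(x_i)`` holds to floating-point precision for any
  number of sampled orderings; sampling error affects only how the total is
  apportioned.  Orderings are drawn in antithetic pairs (each ordering and
  its reverse) to reduce variance.
"""

from __future__ import annotations

import numpy as np


def linear_shapley(coef: np.ndarray, intercept: float, X: np.ndarray, background_mean: np.ndarray):
    """Exact Shapley values of a linear model w.r.t. a background mean."""
    coef = np.asarray(coef, dtype=float)
    X = np.asarray(X, dtype=float)
    background_mean = np.asarray(background_mean, dtype=float)
    phi = coef[None, :] * (X - background_mean[None, :])
    base = float(intercept + coef @ background_mean)
    return phi, base


def permutation_shapley(
    predict,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 4,
    rng: np.random.Generator | None = None,
):
    """Permutation-sampling Shapley values.

    Parameters
    ----------
    predict : callable mapping (m, F) arrays to length-m predictions
    X : (S, F) samples to explain
    background : (B, F) reference rows defining the baseline expectation
    n_permutations : number of sampled feature orderings (rounded up to an
        even count; orderings come in antithetic forward/reverse pairs)

    Returns ``(phi, base)`` with ``phi`` of shape (S, F) and scalar ``base``
    equal to the mean prediction over the background.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    S, F = X.shape
    B = background.shape[0]

    base = float(np.mean(predict(background)))
    orders = []
    for _ in range((n_permutations + 1) // 2):
        perm = rng.permutation(F)
        orders.append(perm)
        orders.append(perm[::-1])
    orders = orders[: max(n_permutations, 1)]

    phi = np.zeros((S, F))
    x_rep = np.repeat(X, B, axis=0)  # (S*B, F), sample-major
    for order in orders:
        Z = np.tile(background, (S, 1))
        prev = np.full(S, base)
        for j in order:
            Z[:, j] = x_rep[:, j]
            v = predict(Z).reshape(S, B).mean(axis=1)
            phi[:, j] += v - prev
            prev = v
    phi /= len(orders)
    return phi, base
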
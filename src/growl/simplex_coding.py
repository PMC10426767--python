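"""Angle-based simplex coding of treatment groups.

K treatment groups are encoded as the K vertices ``W_1 .. W_K`` of a regular
simplex centred at the origin of ``R^{K-1}``:

.. math::

    W_1 = (K-1)^{-1/2}\\,\\mathbf{1}_{K-1}, \\qquad
    W_k = -\\frac{1+\\sqrt{K}}{(K-1)^{3/2}}\\,\\mathbf{1}_{K-1}
          + \\sqrt{\\frac{K}{K-1}}\\, e_{k-1}, \\quad k = 2..K.

Every vertex has unit norm, any two distinct vertices have inner product
``-1/(K-1)``, and the vertices sum to zero.  A decision function
``f : X -> R^{K-1}`` induces the group rule ``argmax_k <W_k, f(x)>``; for
``K = 2`` this reduces to the usual sign coding ``W = (+1, -1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimplexCode", "build_simplex", "decide_group"]


@dataclass(frozen=True)
class SimplexCode:
    """The K unit-norm class-code vectors of the regular simplex in R^{K-1}.

    Attributes
    ----------
    K : int
        Number of treatment groups (>= 2).
    W : ndarray of shape (K, K-1)
        Row ``k-1`` is the code vector of group ``k``.
    """

    K: int
    W: np.ndarray = field(repr=False)

    @property
    def gram(self) -> np.ndarray:
        """K x K matrix of pairwise inner products <W_j, W_k>."""
        return self.W @ self.W.T


def build_simplex(K: int) -> SimplexCode:
    """Construct the simplex code for ``K`` groups.

    Raises
    ------
    ValueError
        If ``K < 2``.
    """
    if not isinstance(K, (int, np.integer)) or K < 2:
        raise ValueError(f"simplex coding needs an integer K >= 2, got {K!r}")
    K = int(K)
    W = np.empty((K, K - 1))
    W[0] = (K - 1) ** -0.5
    W[1:] = -(1.0 + np.sqrt(K)) / (K - 1) ** 1.5
    idx = np.arange(1, K)
    W[idx, idx - 1] += np.sqrt(K / (K - 1.0))
    return SimplexCode(K=K, W=W)


def decide_group(code: SimplexCode, f_value: np.ndarray) -> int:
    """Group assigned to a decision-function value: ``argmax_k <W_k, f>``.

    Ties are broken toward the smallest group index, so the zero function
    always recommends group 1.  Returns a label in ``1..K``.
    """
    f_value = np.asarray(f_value, dtype=float)
    if f_value.shape != (code.K - 1,):
        raise ValueError(
            f"f_value must have length K-1={code.K - 1}, got shape {f_value.shape}"
        )
    scores = code.W @ f_value
    return int(np.argmax(scores)) + 1


def decide_groups(code: SimplexCode, f_values: np.ndarray) -> np.ndarray:
    """Vectorised :func:`decide_group` over rows of an (m, K-1) array."""
    f_values = np.atleast_2d(np.asarray(f_values, dtype=float))
    if f_values.shape[1] != code.K - 1:
        raise ValueError(
            f"f_values must have K-1={code.K - 1} columns, got {f_values.shape[1]}"
        )
    return np.argmax(f_values @ code.W.T, axis=1) + 1
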
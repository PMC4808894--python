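"""Method-of-moments variance components for balanced repeated measures.

One-way random-effects ANOVA on the transformed scale: with n persons and
k days each,

    MSW = sum_ij (y_ij - ybar_i)^2 / (n (k - 1))       -> sigma_eps^2
    MSB = k * sum_i (ybar_i - ybar)^2 / (n - 1)
    sigma_u^2 = (MSB - MSW) / k, truncated at 0.

The moment estimator is used by all three usual-intake estimators; on the
balanced intercept-only two-day design it coincides closely with REML and
keeps the methods comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VarianceComponents", "estimate_components"]

#: a between-person variance estimate below this is treated as exactly zero
#: (this is what triggers the degenerate-sample exclusion rule downstream).
ZERO_TOL = 1e-12


@dataclass(frozen=True)
class VarianceComponents:
    """Fitted transformed-scale model: mean and the two variances."""

    mu_hat: float
    sigma_u_sq_hat: float
    sigma_eps_sq_hat: float
    truncated: bool

    def __post_init__(self) -> None:
        if self.sigma_eps_sq_hat < 0 or self.sigma_u_sq_hat < 0:
            raise ValueError("variance estimates must be >= 0")
        if self.truncated and self.sigma_u_sq_hat != 0:
            raise ValueError("truncated flag requires sigma_u_sq_hat == 0")


def estimate_components(transformed) -> VarianceComponents:
    """Balanced one-way ANOVA moment estimates from per-person replicates.

    Parameters
    ----------
    transformed : array-like, shape (n, k)
        Transformed daily values; every person must have the same k >= 2.

    Returns
    -------
    VarianceComponents
        ``truncated`` is set when the raw between-person estimate fell at
        or below zero (within ``ZERO_TOL``) and was clamped.
    """
    y = np.asarray(transformed, dtype=float)
    if y.ndim != 2:
        raise ValueError("expected a rectangular (n, k) array; input is unbalanced")
    n, k = y.shape
    if n < 2:
        raise ValueError("need at least 2 persons")
    if k < 2:
        raise ValueError("need at least 2 replicates per person")

    person_means = y.mean(axis=1)
    grand = float(y.mean())
    msw = float(((y - person_means[:, None]) ** 2).sum() / (n * (k - 1)))
    msb = float(k * ((person_means - grand) ** 2).sum() / (n - 1))
    raw_between = (msb - msw) / k

    if raw_between < ZERO_TOL:
        return VarianceComponents(grand, 0.0, msw, truncated=True)
    return VarianceComponents(grand, raw_between, msw, truncated=False)
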
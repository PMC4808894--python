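"""Box-Cox power transforms and data-driven selection of the exponent.

The one-parameter transform ``((x)^lam - 1)/lam`` (``log x`` at ``lam = 0``)
is used by the SPADE- and NCI-style estimators; the two-parameter variant
adds a non-negative shift ``c`` applied before transforming and is used by
the MSM-style estimator, whose exponent is restricted to reciprocals of
small integers (``1/lam = 1, 2, 3, ...``).

Selection of ``lam`` maximizes the normal profile log-likelihood of the
transformed values including the Jacobian term ``(lam - 1) * sum(log x)``
(:func:`scipy.stats.boxcox_llf`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BoxCoxParams",
    "forward",
    "inverse",
    "fit_lambda_mle",
    "fit_lambda_restricted",
]

#: lower end of the free-lambda search interval; kept strictly positive so the
#: optimizer never crosses the lam=0 (log) branch discontinuity.
LAM_SEARCH_MIN = 0.01
LAM_SEARCH_MAX = 1.0


@dataclass(frozen=True)
class BoxCoxParams:
    """A fitted or specified Box-Cox transform.

    Parameters
    ----------
    lam : float
        Exponent, in ``[0, 1]``; ``0`` means the log transform.
    shift : float
        Additive shift applied before transforming (``0`` for the
        one-parameter transform).
    """

    lam: float
    shift: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lam must lie in [0, 1], got {self.lam}")
        if self.shift < 0:
            raise ValueError(f"shift must be >= 0, got {self.shift}")


def forward(x, params: BoxCoxParams):
    """Apply the Box-Cox transform to positive data.

    Accepts scalars or arrays; raises on any ``x + shift <= 0``.
    """
    x = np.asarray(x, dtype=float)
    z = x + params.shift
    if np.any(z <= 0):
        raise ValueError("Box-Cox transform requires x + shift > 0")
    if params.lam == 0.0:
        out = np.log(z)
    else:
        out = (np.power(z, params.lam) - 1.0) / params.lam
    return out if out.ndim else float(out)


def inverse(y, params: BoxCoxParams):
    """Invert the Box-Cox transform, clamping out-of-domain values to 0.

    For ``lam > 0`` the inverse ``(lam*y + 1)^(1/lam) - shift`` only exists
    when ``lam*y + 1 > 0``; outside that region the result is 0 (intakes are
    non-negative, and the clamp is what the quadrature back-transformation
    relies on in the far lower tail).  The result is floored at 0.
    """
    y = np.asarray(y, dtype=float)
    if params.lam == 0.0:
        out = np.exp(y) - params.shift
    else:
        base = params.lam * y + 1.0
        out = np.where(
            base > 0.0,
            np.power(np.clip(base, 0.0, None), 1.0 / params.lam) - params.shift,
            0.0,
        )
    out = np.clip(out, 0.0, None)
    return out if out.ndim else float(out)


def _check_fit_input(values: np.ndarray, min_n: int = 10) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if values.size < min_n:
        raise ValueError(f"need at least {min_n} values to fit lambda")
    return values


def fit_lambda_mle(values) -> BoxCoxParams:
    """Free maximum-likelihood selection of the one-parameter exponent.

    Maximizes the Jacobian-corrected normal profile log-likelihood over
    ``lam`` in ``[0.01, 1]`` with a bounded scalar minimizer.

    Parameters
    ----------
    values : array-like
        At least 10 strictly positive observations.
    """
    values = _check_fit_input(values)
    if np.any(values <= 0):
        raise ValueError("free-lambda MLE requires strictly positive values")

    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, values),
        bounds=(LAM_SEARCH_MIN, LAM_SEARCH_MAX),
        method="bounded",
        options={"xatol": 1e-5},
    )
    return BoxCoxParams(lam=float(res.x), shift=0.0)


def fit_lambda_restricted(values, candidate_denoms=range(1, 11)) -> BoxCoxParams:
    """Restricted-grid selection: ``lam = 1/d`` over integer denominators.

    If any value is non-positive a shift ``-min + 1e-6 * range`` is applied
    first, so the transform is always defined.  The winning ``lam`` maximizes
    the same Jacobian-corrected profile log-likelihood on the shifted data.
    """
    values = _check_fit_input(values)
    if np.ptp(values) == 0:
        raise ValueError("all values identical; likelihood is degenerate")

    denoms = [int(d) for d in candidate_denoms]
    if not denoms or any(d < 1 for d in denoms):
        raise ValueError("candidate denominators must be positive integers")

    vmin = values.min()
    shift = 0.0 if vmin > 0 else -vmin + 1e-6 * np.ptp(values)
    shifted = values + shift

    best_lam, best_llf = None, -np.inf
    for d in denoms:
        lam = 1.0 / d
        llf = float(stats.boxcox_llf(lam, shifted))
        if llf > best_llf:
            best_lam, best_llf = lam, llf
    return BoxCoxParams(lam=best_lam, shift=shift)
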
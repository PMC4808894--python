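"""True usual-intake distribution implied by the generating parameters.

Given the transformed-scale parameters (mu, sigma_u^2, sigma_eps^2, lam),
the usual intake of a person with transformed-scale mean t is the
within-person-noise-integrated back-transform

    U(t) = E[ invBC(t + eps) ],  eps ~ Normal(0, sigma_eps^2),

evaluated by Gauss-Hermite quadrature.  The true percentile p of the
usual-intake distribution is then U(mu + z_p * sigma_u) (U is monotone in
t), and the true mean integrates over the total variance
sigma_u^2 + sigma_eps^2.

For lam = 1/r with integer r the integrand is a degree-r polynomial, so
the quadrature is exact at >= ceil((r+1)/2) nodes; :func:`closed_form_mean`
provides the independent binomial/normal-moment cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .boxcox import BoxCoxParams
from .estimators import backtransform_quadrature
from .scenario_sim import ScenarioSpec

__all__ = ["TrueDistribution", "true_distribution", "closed_form_mean"]

DEFAULT_NODES = 150
DEFAULT_PROBS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)


@dataclass(frozen=True)
class TrueDistribution:
    """True original-scale mean and percentiles of usual intake."""

    mean: float
    percentiles: dict[float, float]

    def statistic(self, name: str) -> float:
        """Fetch 'mean' or 'P<xx>' (e.g. 'P10', 'P50')."""
        if name == "mean":
            return self.mean
        p = float(name.lstrip("P")) / 100.0
        return self.percentiles[p]


def true_distribution(
    spec: ScenarioSpec,
    probs=DEFAULT_PROBS,
    nodes: int = DEFAULT_NODES,
) -> TrueDistribution:
    """Compute the true mean and percentiles by quadrature back-transform."""
    params = BoxCoxParams(lam=spec.lam)
    su = np.sqrt(spec.sigma_u_sq)
    se = np.sqrt(spec.sigma_eps_sq)
    total_sd = np.sqrt(spec.total_variance)

    mean = backtransform_quadrature(spec.mu, total_sd, params, nodes)
    percentiles = {
        float(p): backtransform_quadrature(
            spec.mu + stats.norm.ppf(p) * su, se, params, nodes
        )
        for p in probs
    }
    return TrueDistribution(mean=mean, percentiles=percentiles)


def closed_form_mean(spec: ScenarioSpec) -> float:
    """Exact mean via binomial expansion of E[(lam*Y + 1)^r].

    Requires ``1/lam`` to be a positive integer r.  With
    ``Y ~ Normal(mu, total variance)``, ``m = lam*mu + 1`` and
    ``s = lam * total sd``, odd central normal moments vanish and

        E[(m + s*Z)^r] = sum_{j even} C(r, j) m^(r-j) s^j (j-1)!!
    """
    r_float = 1.0 / spec.lam
    r = round(r_float)
    if abs(r_float - r) > 1e-9 or r < 1:
        raise ValueError(f"1/lam must be a positive integer, got {r_float}")

    m = spec.lam * spec.mu + 1.0
    s = spec.lam * np.sqrt(spec.total_variance)
    total = 0.0
    for j in range(0, r + 1, 2):
        double_fact = 1.0
        for t in range(j - 1, 0, -2):
            double_fact *= t
        total += comb(r, j) * m ** (r - j) * s**j * double_fact
    return float(total)
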
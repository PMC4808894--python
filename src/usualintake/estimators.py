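"""Usual-intake distribution estimators: SPADE-, NCI-, and MSM-style.

Each estimator maps a balanced repeated-intake dataset to an estimated
mean and set of percentiles of the usual-intake distribution on the
original scale.  All three share the same skeleton — Box-Cox transform,
one-way random-effects variance components, back-transformation that
integrates out the within-person (day-to-day) noise — and differ in how
the transform's exponent is chosen and how the back-transformation and
the person-level distribution are computed:

* SPADE-style: free-MLE lambda; percentile p is the Gauss-Hermite
  back-transform of ``mu_hat + z_p * sigma_u_hat`` over the within-person
  noise; the mean back-transforms ``mu_hat`` over the total variance.
* NCI-style: free-MLE lambda; simulates k pseudo-persons from
  ``Normal(mu_hat, sigma_u_sq_hat)``, back-transforms each with a fixed
  9-node rule, and reads mean/percentiles off the simulated sample.
* MSM-style: restricted lambda (1/lambda integer, with shift); shrinks
  each observed person mean toward the grand mean by the reliability
  factor ``sigma_u^2 / (sigma_u^2 + sigma_eps^2 / k)``, back-transforms
  each shrunken mean with a closed moment formula, and reads the
  distribution off the n persons.

A sample whose between-person variance is estimated as zero yields a
degenerate estimate (all percentiles equal); downstream evaluation
excludes such samples for all methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats as _stats

from .boxcox import BoxCoxParams, fit_lambda_mle, fit_lambda_restricted, forward, inverse
from .scenario_sim import IntakeDataset
from .varcomp import VarianceComponents, estimate_components

__all__ = [
    "EstimatorConfig",
    "UsualIntakeEstimate",
    "backtransform_quadrature",
    "backtransform_closed_form",
    "estimate_spade",
    "estimate_nci",
    "estimate_msm",
    "estimate_all",
    "METHODS",
]

#: node count of the NCI-style back-transformation ("9-point approximation");
#: exact for polynomial integrands up to degree 17.
NCI_NODES = 9

DEFAULT_PROBS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunable knobs shared by the estimators.

    percentile_probs : probabilities at which percentiles are reported
    gh_nodes         : Gauss-Hermite node count for SPADE-style quadrature
    nci_pseudo_persons : simulated-person count k of the NCI-style method
    nci_seed         : seed of the NCI-style pseudo-person draw
    msm_denoms       : candidate integer denominators for the restricted lambda
    """

    percentile_probs: tuple = DEFAULT_PROBS
    gh_nodes: int = 60
    nci_pseudo_persons: int = 50_000
    nci_seed: int = 0
    msm_denoms: tuple = tuple(range(1, 11))

    def __post_init__(self) -> None:
        if self.gh_nodes < 3:
            raise ValueError("gh_nodes must be >= 3")
        if self.nci_pseudo_persons < 1000:
            raise ValueError("nci_pseudo_persons must be >= 1000")


@dataclass(frozen=True)
class UsualIntakeEstimate:
    """One method's estimated usual-intake distribution for one sample."""

    method: str
    mean: float
    percentiles: dict[float, float]
    lam_hat: float
    components: VarianceComponents
    degenerate: bool
    shift: float = 0.0

    def statistic(self, name: str) -> float:
        """Fetch 'mean' or 'P<xx>' (e.g. 'P10')."""
        if name == "mean":
            return self.mean
        return self.percentiles[float(name.lstrip("P")) / 100.0]


# -- back-transformations -----------------------------------------------------

def backtransform_quadrature(t, sigma_eps: float, params: BoxCoxParams, nodes: int):
    """Within-noise-integrated back-transform by Gauss-Hermite quadrature.

        BT(t) = sum_m w_m * invBC(t + sqrt(2) * sigma_eps * x_m) / sqrt(pi)

    over the Gauss-Hermite nodes/weights (x_m, w_m).  Equals the plain
    inverse transform when ``sigma_eps = 0``.  Accepts scalar or array t.
    """
    if sigma_eps < 0:
        raise ValueError("sigma_eps must be >= 0")
    if nodes < 3:
        raise ValueError("nodes must be >= 3")
    t = np.asarray(t, dtype=float)
    if sigma_eps == 0.0:
        return inverse(t, params)
    x, w = np.polynomial.hermite.hermgauss(nodes)
    vals = inverse(t[..., None] + np.sqrt(2.0) * sigma_eps * x, params)
    out = vals @ w / np.sqrt(np.pi)
    return out if out.ndim else float(out)


def backtransform_closed_form(t, sigma_eps: float, params: BoxCoxParams):
    """Closed-moment back-transform for ``lam = 1/r`` with integer r.

    E[((lam*(t + eps) + 1)^r] with eps ~ Normal(0, sigma_eps^2) expands by
    the binomial theorem; odd central normal moments vanish, leaving

        sum_{m even} C(r, m) (lam*t + 1)^(r-m) (lam*sigma_eps)^m (m-1)!!

    minus the shift, floored at 0.  Accepts scalar or array t.
    """
    if sigma_eps < 0:
        raise ValueError("sigma_eps must be >= 0")
    r_float = 1.0 / params.lam
    r = round(r_float)
    if abs(r_float - r) > 1e-9 or r < 1:
        raise ValueError(f"1/lam must be a positive integer, got {r_float}")

    t = np.asarray(t, dtype=float)
    base = params.lam * t + 1.0
    total = np.zeros_like(base)
    for m in range(0, r + 1, 2):
        double_fact = 1.0
        for j in range(m - 1, 0, -2):
            double_fact *= j
        total += comb(r, m) * base ** (r - m) * (params.lam * sigma_eps) ** m * double_fact
    out = np.clip(total - params.shift, 0.0, None)
    return out if out.ndim else float(out)


# -- shared plumbing ----------------------------------------------------------

def _fit_free(data: IntakeDataset):
    """Free-lambda fit + variance components (SPADE/NCI first stages)."""
    amounts = data.amounts_by_person()
    params = fit_lambda_mle(amounts.ravel())
    transformed = forward(amounts, params)
    comps = estimate_components(transformed)
    return params, comps


def _monotone_percentiles(probs, values) -> dict[float, float]:
    """Map probs to values, repairing sub-ulp rounding inversions."""
    order = np.argsort(probs)
    probs = np.asarray(probs, dtype=float)[order]
    fixed = np.maximum.accumulate(np.asarray(values, dtype=float)[order])
    return {float(p): float(v) for p, v in zip(probs, fixed)}


def _empirical_quantiles(values: np.ndarray, probs) -> dict[float, float]:
    # linear interpolation of order statistics at position p*(n-1)+1
    qs = np.quantile(values, list(probs), method="linear")
    return _monotone_percentiles(probs, qs)


# -- estimators ---------------------------------------------------------------

def estimate_spade(data: IntakeDataset, config: EstimatorConfig = EstimatorConfig()) -> UsualIntakeEstimate:
    """SPADE-style estimate: direct quadrature back-transform of the model.

    Percentile p = BT(mu_hat + z_p * sigma_u_hat) over the within-person
    noise; the mean back-transforms mu_hat over the total variance.
    """
    params, comps = _fit_free(data)
    su = np.sqrt(comps.sigma_u_sq_hat)
    se = np.sqrt(comps.sigma_eps_sq_hat)
    total_sd = np.sqrt(comps.sigma_u_sq_hat + comps.sigma_eps_sq_hat)

    z = _stats.norm.ppf(list(config.percentile_probs))
    vals = backtransform_quadrature(
        comps.mu_hat + z * su, se, params, config.gh_nodes
    )
    percentiles = _monotone_percentiles(config.percentile_probs, vals)
    mean = float(backtransform_quadrature(comps.mu_hat, total_sd, params, config.gh_nodes))
    return UsualIntakeEstimate(
        method="spade",
        mean=mean,
        percentiles=percentiles,
        lam_hat=params.lam,
        components=comps,
        degenerate=comps.sigma_u_sq_hat == 0.0,
    )


def estimate_nci(data: IntakeDataset, config: EstimatorConfig = EstimatorConfig()) -> UsualIntakeEstimate:
    """NCI-style estimate: simulated pseudo-persons, 9-node back-transform.

    Draws ``config.nci_pseudo_persons`` values from
    ``Normal(mu_hat, sigma_u_sq_hat)`` (seeded by ``config.nci_seed``),
    back-transforms each with the fixed 9-node rule and the within-person
    sd, then reads the mean and interpolated empirical quantiles off the
    simulated sample.
    """
    params, comps = _fit_free(data)
    rng = np.random.default_rng(config.nci_seed)
    b = comps.mu_hat + np.sqrt(comps.sigma_u_sq_hat) * rng.standard_normal(
        config.nci_pseudo_persons
    )
    usual = backtransform_quadrature(
        b, np.sqrt(comps.sigma_eps_sq_hat), params, NCI_NODES
    )
    return UsualIntakeEstimate(
        method="nci",
        mean=float(usual.mean()),
        percentiles=_empirical_quantiles(usual, config.percentile_probs),
        lam_hat=params.lam,
        components=comps,
        degenerate=comps.sigma_u_sq_hat == 0.0,
    )


def estimate_msm(data: IntakeDataset, config: EstimatorConfig = EstimatorConfig()) -> UsualIntakeEstimate:
    """MSM-style estimate: shrinkage of person means, closed back-transform.

    First stage is an intercept-only regression on the original scale
    (fitted value = grand mean), so the working values
    ``e_ij = x_ij - fitted_ij + xbar`` equal the observations; the plumbing
    is kept so a covariate stage can slot in later.  A restricted
    two-parameter Box-Cox transform (1/lambda integer, shift if needed) is
    fitted to the working values; variance components come from the
    transformed values; each person's transformed mean is shrunk toward
    the grand mean by the reliability factor
    ``sigma_u^2 / (sigma_u^2 + sigma_eps^2 / k)`` and back-transformed by
    the closed moment formula.
    """
    amounts = data.amounts_by_person()
    n, k = amounts.shape
    grand_original = float(amounts.mean())
    fitted = np.full(n, grand_original)  # intercept-only first stage
    working = amounts - grand_original + grand_original  # e_ij = x_ij here

    params = fit_lambda_restricted(working.ravel(), config.msm_denoms)
    transformed = forward(working, params)
    comps = estimate_components(transformed)

    if comps.sigma_u_sq_hat == 0.0:
        shrink = 0.0
    else:
        shrink = comps.sigma_u_sq_hat / (
            comps.sigma_u_sq_hat + comps.sigma_eps_sq_hat / k
        )
    person_means = transformed.mean(axis=1)
    t_shrunk = comps.mu_hat + (person_means - comps.mu_hat) * shrink

    bt = backtransform_closed_form(t_shrunk, np.sqrt(comps.sigma_eps_sq_hat), params)
    usual = np.clip(fitted - grand_original + bt, 0.0, None)
    return UsualIntakeEstimate(
        method="msm",
        mean=float(usual.mean()),
        percentiles=_empirical_quantiles(usual, config.percentile_probs),
        lam_hat=params.lam,
        components=comps,
        degenerate=comps.sigma_u_sq_hat == 0.0,
        shift=params.shift,
    )


METHODS = {
    "spade": estimate_spade,
    "nci": estimate_nci,
    "msm": estimate_msm,
}


def estimate_all(data: IntakeDataset, config: EstimatorConfig = EstimatorConfig()) -> dict[str, UsualIntakeEstimate]:
    """Run all three estimators on one dataset."""
    return {name: fn(data, config) for name, fn in METHODS.items()}
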
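"""Univariate ACE variance decomposition for extended twin-family data.

The phenotype of family members is modeled as multivariate normal with mean
``X @ beta`` (intercept, sex, age, optionally total brain volume) and
covariance ``A * K_A + C * K_C + E * I``, where K_A carries coefficients of
1.0 between MZ co-twins and 0.5 between DZ twins/full siblings, and K_C is
1.0 within a family. Estimation is full-information maximum likelihood over
all families, including singletons, with missing phenotypes marginalized
out.

Variance components are parameterized as squared path coefficients
(A = a^2 and so on), which keeps them non-negative without constrained
optimization and makes the zero boundary exactly reachable. Nested-submodel
tests use the boundary-corrected chi-square mixtures (50:50 for one dropped
component; 25:50:25 on 0/1/2 degrees of freedom for dropping A and C
together). Confidence intervals are profile-likelihood based: a bound is
the extreme value of the quantity whose constrained-optimum -2 lnL sits
3.841 (chi-square 1 df, 95%) above the unconstrained minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._fiml import NONPD_PENALTY, FamilyDataset, ols_start
from .reshape import FamilyRecord, RelatednessCoefficients

__all__ = [
    "VarianceComponents",
    "ACEFit",
    "ProfileCI",
    "TestResult",
    "MODELS",
    "expected_family_cov",
    "family_loglik",
    "fit_ace",
    "standardize",
    "profile_ci",
    "lrt",
]

#: Free path coefficients per model variant.
MODELS = {"ACE": ("a", "c", "e"), "AE": ("a", "e"), "CE": ("c", "e"), "E": ("e",)}

CHI2_95_1DF = float(stats.chi2.ppf(0.95, 1))  # 3.841...


@dataclass(frozen=True)
class VarianceComponents:
    """Unstandardized A, C, E variances (trait units squared)."""

    A: float
    C: float
    E: float

    def __post_init__(self) -> None:
        if min(self.A, self.C, self.E) < 0:
            raise ValueError("variance components must be non-negative")
        if self.V <= 0:
            raise ValueError("total variance must be positive")

    @property
    def V(self) -> float:
        return self.A + self.C + self.E


@dataclass(frozen=True)
class ACEFit:
    """Result of one univariate fit."""

    model: str
    trait: str
    components: VarianceComponents
    a2: float
    c2: float
    e2: float
    mean_betas: dict[str, float]
    minus2lnl: float
    n_params: int
    n_families: int
    converged: bool
    start_spread: float = field(default=np.nan, compare=False)


@dataclass(frozen=True)
class ProfileCI:
    quantity: str
    lower: float
    upper: float
    level: float = 0.95
    trusted: bool = True


@dataclass(frozen=True)
class TestResult:
    """Likelihood-ratio test of a dropped component (or covariance path)."""

    name: str
    deviance: float
    df_dropped: int
    p_value: float
    q_value: float | None = None


def expected_family_cov(
    components: VarianceComponents, rel: RelatednessCoefficients
) -> np.ndarray:
    """Model-implied m x m phenotype covariance for one family."""
    m = rel.rA.shape[0]
    return components.A * rel.rA + components.C * rel.rC + components.E * np.eye(m)


def family_loglik(
    record: FamilyRecord,
    components: VarianceComponents,
    beta: np.ndarray,
) -> float:
    """Log-likelihood contribution of one family at the given parameters.

    Missing entries are marginalized (rows/columns subset); a non-PD
    covariance at the evaluated point yields ``-inf`` rather than raising.
    """
    obs = ~np.isnan(record.y)
    if not obs.any():
        return 0.0
    sigma = expected_family_cov(components, record.relatedness)[np.ix_(obs, obs)]
    mu = (record.X @ np.asarray(beta))[obs]
    try:
        return float(
            stats.multivariate_normal.logpdf(record.y[obs], mean=mu, cov=sigma)
        )
    except np.linalg.LinAlgError:
        return -np.inf
    except ValueError:  # scipy rejects non-PSD covariance
        return -np.inf


def _start_proportions(model: str, n_starts: int, rng: np.random.Generator):
    base = {
        "ACE": [(1 / 3, 1 / 3, 1 / 3), (0.6, 0.05, 0.35), (0.05, 0.6, 0.35),
                (0.85, 0.05, 0.1), (0.2, 0.2, 0.6)],
        "AE": [(0.5, 0.0, 0.5), (0.8, 0.0, 0.2), (0.2, 0.0, 0.8)],
        "CE": [(0.0, 0.5, 0.5), (0.0, 0.8, 0.2), (0.0, 0.2, 0.8)],
        "E": [(0.0, 0.0, 1.0)],
    }[model]
    starts = list(base)
    while len(starts) < n_starts:
        w = rng.dirichlet(np.ones(3))
        free = MODELS[model]
        w = np.array([w[0] if "a" in free else 0.0,
                      w[1] if "c" in free else 0.0, w[2]])
        w[2] = max(w[2], 0.05)
        starts.append(tuple(w / w.sum()))
    return starts[:n_starts]


def fit_ace(
    records: list[FamilyRecord],
    model: str = "ACE",
    trait: str | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> ACEFit:
    """Fit a univariate ACE (or nested AE/CE/E) model by FIML.

    ``records`` must carry exactly one trait. Optimization is quasi-Newton
    (BFGS, numerical gradients) from ``n_starts`` seeded starting points on
    an internally standardized phenotype scale (results are invariant to
    trait rescaling); the best -2 lnL is kept and convergence additionally
    requires the two best starts to agree to 1e-4 when more than one start
    is run.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(MODELS)}")
    beta0, v0 = ols_start(records, 0)
    sd = float(np.sqrt(v0))
    ds = FamilyDataset(records, y_scale=[sd])
    if ds.n_traits != 1:
        raise ValueError("univariate fit requires single-trait records")
    trait = trait or ds.trait_names[0]
    n_informative = sum(
        g["Y"].shape[0] for g in ds.groups if g["kA"].shape[0] > 1
    )
    if model in ("ACE", "AE", "CE") and n_informative < 2:
        import warnings

        warnings.warn("fewer than 2 relative pairs: A/C separation is weakly identified")

    p = ds.n_covariates
    free = MODELS[model]
    rng = np.random.default_rng(seed)

    def unpack(theta):
        beta = theta[:p].reshape(1, p)
        paths = dict.fromkeys(("a", "c", "e"), 0.0)
        for k, name in enumerate(free):
            paths[name] = theta[p + k]
        return beta, paths

    def neg2ll(theta):
        beta, paths = unpack(theta)
        return ds.neg2ll(
            beta,
            np.array([[paths["a"] ** 2]]),
            np.array([[paths["c"] ** 2]]),
            np.array([[paths["e"] ** 2]]),
        )

    results = []
    for props in _start_proportions(model, n_starts, rng):
        paths0 = [np.sqrt(max(pr, 1e-4)) for pr, name in zip(props, ("a", "c", "e"))
                  if name in free]
        x0 = np.concatenate([beta0 / sd, paths0])
        res = optimize.minimize(neg2ll, x0, method="BFGS",
                                options={"gtol": 1e-5, "maxiter": 500})
        if np.isfinite(res.fun) and res.fun < NONPD_PENALTY / 2:
            results.append(res)
    if not results:
        raise RuntimeError(f"FIML optimization failed for trait {trait!r} ({model})")

    results.sort(key=lambda r: r.fun)
    best = results[0]
    spread = results[1].fun - best.fun if len(results) > 1 else 0.0
    grad_ok = np.max(np.abs(best.jac)) < 1e-3 if best.jac is not None else False
    converged = bool(best.success or grad_ok) and (len(results) < 2 or spread < 1e-4)

    beta, paths = unpack(best.x)
    comp = VarianceComponents(
        A=paths["a"] ** 2 * v0, C=paths["c"] ** 2 * v0, E=paths["e"] ** 2 * v0
    )
    a2, c2, e2 = standardize(comp)
    betas = dict(zip(records[0].covariate_names, beta.ravel() * sd))
    return ACEFit(
        model=model,
        trait=trait,
        components=comp,
        a2=a2,
        c2=c2,
        e2=e2,
        mean_betas=betas,
        minus2lnl=float(best.fun) + ds.neg2ll_offset,
        n_params=p + len(free),
        n_families=ds.n_families,
        converged=converged,
        start_spread=float(spread),
    )


def standardize(components: VarianceComponents) -> tuple[float, float, float]:
    """Proportions (a2, c2, e2) = components divided by total variance V."""
    v = components.V
    if v <= 0:
        raise ValueError("total variance must be positive to standardize")
    return components.A / v, components.C / v, components.E / v


_PROPORTIONS = {"a2": 0, "c2": 1, "e2": 2}
_COMPONENTS = {"A": 0, "C": 1, "E": 2}


def _quantity_fn(quantity: str, p: int, v_scale: float = 1.0):
    """Map a (standardized-scale) parameter vector to the profiled quantity.

    Proportions are scale-free; raw components are mapped back to original
    trait units via ``v_scale`` (the squared standardization factor).
    """
    if quantity in _PROPORTIONS:
        k = _PROPORTIONS[quantity]

        def fn(theta):
            comps = theta[p:] ** 2
            return comps[k] / comps.sum()

    elif quantity in _COMPONENTS:
        k = _COMPONENTS[quantity]

        def fn(theta):
            return theta[p + k] ** 2 * v_scale

    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return fn


def profile_ci(
    records: list[FamilyRecord],
    fit: ACEFit,
    quantity: str = "a2",
    level: float = 0.95,
    tol: float = 1e-3,
) -> ProfileCI:
    """Profile-likelihood confidence interval for a component or proportion.

    The bound satisfies ``min -2lnL s.t. quantity = v  ==  -2lnL_hat +
    chi2_1(level)``; the constrained optimum re-optimizes every other
    parameter (SLSQP with an equality constraint), and the bound value is
    located by bisection to ``tol`` on the quantity scale. Bounds that run
    into the parameter-space edge are reported at the edge (0 or 1 for
    proportions). Only full-ACE fits are profiled.
    """
    if fit.model != "ACE":
        raise ValueError("profile CIs are computed on the full ACE fit")
    _, v0 = ols_start(records, 0)
    sd = float(np.sqrt(v0))
    ds = FamilyDataset(records, y_scale=[sd])
    p = ds.n_covariates
    qfn = _quantity_fn(quantity, p, v_scale=v0)
    crit = float(stats.chi2.ppf(level, 1))
    threshold = fit.minus2lnl + crit

    theta_hat = np.concatenate(
        [
            np.array(list(fit.mean_betas.values())) / sd,
            np.sqrt([fit.components.A, fit.components.C, fit.components.E]) / sd,
        ]
    )
    q_hat = qfn(theta_hat)

    def neg2ll(theta):
        beta = theta[:p].reshape(1, p)
        comps = theta[p:] ** 2
        return ds.neg2ll(beta, np.array([[comps[0]]]), np.array([[comps[1]]]),
                         np.array([[comps[2]]])) + ds.neg2ll_offset

    failed = False

    def feasible_start(v: float) -> np.ndarray:
        """Parameter point satisfying the constraint, keeping total variance."""
        x = theta_hat.copy()
        comps = np.maximum(x[p:] ** 2, 1e-4)
        total = comps.sum()
        if quantity in _PROPORTIONS:
            k = _PROPORTIONS[quantity]
            others = np.delete(comps, k)
            share = others / others.sum()
            comps = np.insert(share * (1.0 - v) * total, k, v * total)
        else:
            k = _COMPONENTS[quantity]
            comps[k] = v / v0  # back to the standardized scale
        x[p:] = np.sqrt(np.maximum(comps, 0.0))
        return x

    def constrained_min(v: float) -> float:
        nonlocal failed
        best = np.inf
        for x0 in (theta_hat, feasible_start(v)):
            res = optimize.minimize(
                neg2ll,
                x0,
                method="SLSQP",
                constraints=[{"type": "eq", "fun": lambda th: qfn(th) - v}],
                options={"maxiter": 200, "ftol": 1e-8},
            )
            if np.isfinite(res.fun) and res.fun < NONPD_PENALTY / 2 and abs(
                qfn(res.x) - v
            ) < 1e-4:
                best = min(best, float(res.fun))
        if not np.isfinite(best):
            failed = True
        return best

    is_proportion = quantity in _PROPORTIONS

    def find_bound(direction: int) -> float:
        if is_proportion:
            edge = 1.0 if direction > 0 else 0.0
        else:
            # expand outward until the deviance crosses the threshold
            width = max(np.sqrt(fit.components.V), 1e-3)
            edge = q_hat
            for _ in range(40):
                edge = edge + direction * width if direction > 0 else max(edge - width, 0.0)
                if edge <= 0.0:
                    edge = 0.0
                    break
                if constrained_min(edge) > threshold:
                    break
                width *= 2.0
        if constrained_min(edge) <= threshold + 1e-9:
            return edge  # likelihood stays flat out to the boundary
        lo, hi = (q_hat, edge) if direction > 0 else (edge, q_hat)
        # invariant: inside (toward q_hat) is below threshold, outside above
        for _ in range(200):
            if hi - lo < tol:
                break
            mid = 0.5 * (lo + hi)
            if constrained_min(mid) > threshold:
                if direction > 0:
                    hi = mid
                else:
                    lo = mid
            else:
                if direction > 0:
                    lo = mid
                else:
                    hi = mid
        return 0.5 * (lo + hi)

    upper = find_bound(+1)
    lower = find_bound(-1)
    if is_proportion:
        lower, upper = max(lower, 0.0), min(upper, 1.0)
    return ProfileCI(quantity=quantity, lower=float(lower), upper=float(upper),
                     level=level, trusted=not failed)


def lrt(full: ACEFit, reduced: ACEFit, tol: float = 1e-6) -> TestResult:
    """Boundary-corrected likelihood-ratio test of nested ACE submodels.

    One dropped variance component (A or C): T ~ 50:50 mixture of a point
    mass at zero and chi-square(1). Two dropped (the AC familial test,
    E-only null): 25:50:25 mixture over chi-square(0, 1, 2).
    """
    pairs = {("ACE", "CE"): "A", ("ACE", "AE"): "C", ("ACE", "E"): "AC",
             ("AE", "E"): "A", ("CE", "E"): "C"}
    name = pairs.get((full.model, reduced.model))
    if name is None:
        raise ValueError(f"{reduced.model} is not a tested submodel of {full.model}")
    df = full.n_params - reduced.n_params
    deviance = reduced.minus2lnl - full.minus2lnl
    if deviance < -tol:
        raise ValueError(
            f"reduced model fits better than full by {-deviance:.3g}: check convergence"
        )
    t = max(deviance, 0.0)
    if t <= tol:
        p = 1.0
    elif df == 1:
        p = 0.5 * stats.chi2.sf(t, 1)
    else:
        p = 0.5 * stats.chi2.sf(t, 1) + 0.25 * stats.chi2.sf(t, 2)
    return TestResult(name=name, deviance=t, df_dropped=df, p_value=float(p))
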
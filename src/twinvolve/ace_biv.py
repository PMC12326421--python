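"""Bivariate Cholesky decomposition of trait-pair covariance.

Two traits are modeled jointly: each 2 x 2 component covariance matrix is
parameterized as ``Sigma_comp = L_comp @ L_comp.T`` with lower-triangular
loadings, guaranteeing positive semi-definiteness. Within a person the
phenotype covariance is ``Sigma_A + Sigma_C + Sigma_E``; across family
members the A block is scaled by the additive relatedness coefficient and
the C block is shared, with no cross-person E covariance.

Derived quantities follow standard behavior-genetic definitions: the
genetic correlation ``rG = A_xy / sqrt(A_x A_y)`` (analogously rC, rE), and
the component contributions to the phenotypic correlation
``pcorA = sqrt(a2_x) * rG * sqrt(a2_y)``, which sum exactly to the
model-implied phenotypic correlation. Because component correlations become
numerically meaningless when the corresponding proportional variance is
tiny, rG/rC/rE carry a defined/undefined flag instead of being clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ._fiml import NONPD_PENALTY, FamilyDataset, ols_start
from .ace_uni import TestResult
from .reshape import FamilyRecord

__all__ = [
    "CholeskyLoadings",
    "ComponentCorrelation",
    "BivariateFit",
    "fit_bivariate",
    "genetic_correlation",
    "pcor",
    "test_cov_path",
]

#: Component variances below this are treated as absent when standardizing.
VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class CholeskyLoadings:
    """Lower-triangular 2 x 2 loadings per component (diagonals >= 0)."""

    La: np.ndarray
    Lc: np.ndarray
    Le: np.ndarray

    def __post_init__(self) -> None:
        for mat in (self.La, self.Lc, self.Le):
            if mat.shape != (2, 2) or abs(mat[0, 1]) > 0:
                raise ValueError("loadings must be 2x2 lower-triangular")


@dataclass(frozen=True)
class ComponentCorrelation:
    """A standardized component covariance, with a definedness flag."""

    value: float
    defined: bool


@dataclass(frozen=True)
class BivariateFit:
    traits: tuple[str, str]
    loadings: CholeskyLoadings
    sigma_a: np.ndarray
    sigma_c: np.ndarray
    sigma_e: np.ndarray
    mean_betas: dict[str, dict[str, float]]
    minus2lnl: float
    n_params: int
    converged: bool
    rG: ComponentCorrelation
    rC: ComponentCorrelation
    rE: ComponentCorrelation
    pcorA: float
    pcorC: float
    pcorE: float

    @property
    def sigma_p(self) -> np.ndarray:
        """Model-implied phenotypic covariance matrix."""
        return self.sigma_a + self.sigma_c + self.sigma_e

    @property
    def phenotypic_correlation(self) -> float:
        sp = self.sigma_p
        return float(sp[0, 1] / np.sqrt(sp[0, 0] * sp[1, 1]))


def genetic_correlation(sigma_a: np.ndarray) -> ComponentCorrelation:
    """Standardize a component covariance matrix to a correlation.

    Returns an undefined flag (value NaN, not propagated silently) when a
    diagonal variance is below ``VARIANCE_FLOOR``; raises on negative
    diagonals, which cannot arise from a Cholesky parameterization.
    """
    ax, ay = float(sigma_a[0, 0]), float(sigma_a[1, 1])
    if ax < 0 or ay < 0:
        raise ValueError("component variances must be non-negative")
    if ax < VARIANCE_FLOOR or ay < VARIANCE_FLOOR:
        return ComponentCorrelation(value=float("nan"), defined=False)
    return ComponentCorrelation(value=float(sigma_a[0, 1] / np.sqrt(ax * ay)), defined=True)


def pcor(prop_x: float, prop_y: float, r_component: float) -> float:
    """Component contribution to the phenotypic correlation:
    sqrt(prop_x) * r * sqrt(prop_y). Deliberately unclipped."""
    for p in (prop_x, prop_y):
        if not 0.0 <= p <= 1.0:
            raise ValueError("variance proportions must be in [0, 1]")
    return float(np.sqrt(prop_x) * r_component * np.sqrt(prop_y))


def _tri(theta3: np.ndarray) -> np.ndarray:
    return np.array([[theta3[0], 0.0], [theta3[1], theta3[2]]])


def _fix_signs(mat: np.ndarray) -> np.ndarray:
    out = mat.copy()
    if out[0, 0] < 0:
        out[:, 0] = -out[:, 0]
    if out[1, 1] < 0:
        out[1, 1] = -out[1, 1]
    return out


def fit_bivariate(
    records: list[FamilyRecord],
    n_starts: int = 5,
    seed: int = 0,
    drop_cross: str | None = None,
) -> BivariateFit:
    """Fit the bivariate Cholesky model by FIML.

    ``records`` must carry exactly the two traits, in (x, y) order — for
    brain-behavior pairs the convention is (ROI, behavior). ``drop_cross``
    fixes the named component's cross-loading at zero (the nested model used
    by :func:`test_cov_path`).
    """
    beta0x, v0x = ols_start(records, 0)
    beta0y, v0y = ols_start(records, 1)
    sds = np.sqrt([v0x, v0y])
    ds = FamilyDataset(records, y_scale=sds)
    if ds.n_traits != 2:
        raise ValueError("bivariate fit requires records built on exactly two traits")
    if drop_cross not in (None, "A", "C", "E"):
        raise ValueError("drop_cross must be one of None, 'A', 'C', 'E'")
    p = ds.n_covariates
    comp_order = ("A", "C", "E")

    free_idx: list[tuple[str, int]] = []
    for comp in comp_order:
        for k in range(3):  # (l11, l21, l22)
            if k == 1 and comp == drop_cross:
                continue
            free_idx.append((comp, k))

    def unpack(theta):
        beta = theta[: 2 * p].reshape(2, p)
        tris = {comp: np.zeros(3) for comp in comp_order}
        for val, (comp, k) in zip(theta[2 * p:], free_idx):
            tris[comp][k] = val
        mats = {comp: _tri(tris[comp]) for comp in comp_order}
        return beta, mats

    def neg2ll(theta):
        beta, mats = unpack(theta)
        return ds.neg2ll(
            beta,
            mats["A"] @ mats["A"].T,
            mats["C"] @ mats["C"].T,
            mats["E"] @ mats["E"].T,
        )

    rng = np.random.default_rng(seed)
    base_props = [(1 / 3, 1 / 3, 1 / 3), (0.6, 0.05, 0.35), (0.2, 0.4, 0.4),
                  (0.8, 0.05, 0.15), (0.1, 0.1, 0.8)]
    results = []
    for s in range(n_starts):
        props = base_props[s % len(base_props)]
        jitter = 1.0 if s < len(base_props) else rng.uniform(0.7, 1.3)
        theta0 = list(np.concatenate([beta0x / sds[0], beta0y / sds[1]]))
        for comp, prop in zip(comp_order, props):
            l0 = np.sqrt(max(prop, 0.02)) * jitter
            tri0 = [l0, 0.0, l0]
            for k in range(3):
                if (comp, k) in free_idx:
                    theta0.append(tri0[k])
        res = optimize.minimize(neg2ll, np.asarray(theta0), method="BFGS",
                                options={"gtol": 1e-5, "maxiter": 1000})
        if np.isfinite(res.fun) and res.fun < NONPD_PENALTY / 2:
            results.append(res)
    if not results:
        raise RuntimeError("bivariate FIML optimization failed for all starts")
    results.sort(key=lambda r: r.fun)
    best = results[0]
    spread = results[1].fun - best.fun if len(results) > 1 else 0.0
    converged = bool(best.success or np.max(np.abs(best.jac)) < 1e-3)
    converged = converged and (len(results) < 2 or spread < 1e-3)

    beta, mats = unpack(best.x)
    rescale = np.diag(sds)
    loadings = CholeskyLoadings(
        La=_fix_signs(rescale @ mats["A"]),
        Lc=_fix_signs(rescale @ mats["C"]),
        Le=_fix_signs(rescale @ mats["E"]),
    )
    s_a = loadings.La @ loadings.La.T
    s_c = loadings.Lc @ loadings.Lc.T
    s_e = loadings.Le @ loadings.Le.T
    s_p = s_a + s_c + s_e
    v = np.diag(s_p)
    props = {comp: (s[0, 0] / v[0], s[1, 1] / v[1])
             for comp, s in zip(comp_order, (s_a, s_c, s_e))}
    corrs = {comp: genetic_correlation(s) for comp, s in
             zip(comp_order, (s_a, s_c, s_e))}
    # contributions use the raw covariance so the identity holds even when a
    # correlation is flagged undefined
    pcors = {comp: float(s[0, 1] / np.sqrt(v[0] * v[1]))
             for comp, s in zip(comp_order, (s_a, s_c, s_e))}

    cov_names = records[0].covariate_names
    betas = {
        trait: dict(zip(cov_names, beta[i] * sds[i]))
        for i, trait in enumerate(ds.trait_names)
    }
    return BivariateFit(
        traits=tuple(ds.trait_names),
        loadings=loadings,
        sigma_a=s_a,
        sigma_c=s_c,
        sigma_e=s_e,
        mean_betas=betas,
        minus2lnl=float(best.fun) + ds.neg2ll_offset,
        n_params=len(best.x),
        converged=converged,
        rG=corrs["A"],
        rC=corrs["C"],
        rE=corrs["E"],
        pcorA=pcors["A"],
        pcorC=pcors["C"],
        pcorE=pcors["E"],
    )


def test_cov_path(
    records: list[FamilyRecord],
    component: str,
    full: BivariateFit | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> TestResult:
    """Likelihood-ratio test of one component's cross-trait covariance path.

    The nested model fixes that component's cross-loading at zero; the
    statistic is referred to chi-square with 1 df (the cross-loading is an
    interior parameter, so no boundary mixture applies).
    """
    if component not in ("A", "C", "E"):
        raise ValueError("component must be 'A', 'C' or 'E'")
    if full is None:
        full = fit_bivariate(records, n_starts=n_starts, seed=seed)
    reduced = fit_bivariate(records, n_starts=n_starts, seed=seed, drop_cross=component)
    deviance = reduced.minus2lnl - full.minus2lnl
    if deviance < -1e-6:
        raise ValueError(
            f"reduced model fits better than full by {-deviance:.3g}: check convergence"
        )
    t = max(deviance, 0.0)
    return TestResult(
        name=component, deviance=t, df_dropped=1, p_value=float(stats.chi2.sf(t, 1))
    )
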
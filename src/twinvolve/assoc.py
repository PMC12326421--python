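"""Phenotypic stage: correlations, brain-behavior regressions, FDR control.

Brain-behavior associations are ordinary linear regressions of a behavioral
score on one ROI volume plus covariates (age, sex, total brain volume by
default), mirroring the phenotypic analysis stage of a twin study before
any genetic modeling; family clustering is deliberately ignored here. Two
effect sizes are reported: the standardized slope (beta in SD units) and
the sign-consistent partial correlation of ROI and behavior given the
covariates, derived from the slope's t statistic.

Multiple-testing control is Benjamini-Hochberg, applied within named test
families by default with a global option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "TestLedger",
    "LedgerConfig",
    "correlation_matrix",
    "cluster_order",
    "fit_brain_behavior",
    "fdr_adjust",
    "build_ledger",
    "replication_ledger_config",
    "save_heatmap",
]


@dataclass(frozen=True)
class AssociationResult:
    roi: str
    behavior: str
    beta_std: float
    r_partial: float
    p_value: float
    n: int
    q_value: float | None = None


def correlation_matrix(
    table: pd.DataFrame, variables: list[str], min_pairs: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix.

    Cells with fewer than ``min_pairs`` complete pairs, or involving a
    constant variable, are flagged as NaN rather than silently zeroed.
    """
    sub = table[variables].astype(float)
    corr = sub.corr(method="pearson", min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    for v in variables:
        col = sub[v].dropna()
        if len(col) and col.nunique() == 1:
            corr.loc[v, :] = np.nan
            corr.loc[:, v] = np.nan
    return corr


def cluster_order(corr: pd.DataFrame) -> list[str]:
    """Deterministic average-linkage (UPGMA) leaf order on distance 1 - r.

    Ties are broken by current cluster order (hence by label order for an
    identity matrix, whose input order is preserved). Used only to reorder
    heatmap axes, so the contract is determinism, not dendrogram export.
    """
    labels = list(corr.index)
    n = len(labels)
    if n <= 2:
        return labels
    dist = 1.0 - corr.to_numpy(dtype=float)
    clusters: list[list[int]] = [[i] for i in range(n)]
    # average linkage over original-observation distances
    while len(clusters) > 1:
        best = (np.inf, -1, -1)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best[0] - 1e-12:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return [labels[i] for i in clusters[0]]


def fit_brain_behavior(
    table: pd.DataFrame,
    roi: str,
    behavior: str,
    covariates: tuple[str, ...] = ("age", "sex", "tbv"),
) -> AssociationResult:
    """Regress ``behavior`` on ``roi`` plus covariates; return effect sizes.

    ``beta_std`` is the slope rescaled by sd(roi)/sd(behavior) on the
    analyzed subsample; ``r_partial`` is t/sqrt(t^2 + df). The p value is
    the two-sided t test of the ROI slope. Requires at least p + 2 complete
    cases and a full-rank design (collinear columns are named on error).
    """
    cols = [behavior, roi, *covariates]
    data = table[cols].dropna()
    n, n_params = len(data), len(covariates) + 2
    if n < n_params + 2:
        raise ValueError(f"only {n} complete cases for {roi} vs {behavior}")
    x = sm.add_constant(data[[roi, *covariates]], has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        bad = [c for c in x.columns[1:]
               if np.linalg.matrix_rank(x.drop(columns=c).to_numpy()) == rank]
        raise ValueError(f"design is rank-deficient; collinear columns: {bad}")
    fit = sm.OLS(data[behavior], x).fit()
    slope = fit.params[roi]
    tval = fit.tvalues[roi]
    df = fit.df_resid
    beta_std = slope * data[roi].std(ddof=1) / data[behavior].std(ddof=1)
    r_partial = float(tval / np.sqrt(tval**2 + df))
    return AssociationResult(
        roi=roi,
        behavior=behavior,
        beta_std=float(beta_std),
        r_partial=r_partial,
        p_value=float(fit.pvalues[roi]),
        n=n,
    )


def fdr_adjust(p_values, family: str = "default") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values for one test family.

    The ``family`` label documents the correction scope; callers apply this
    per analysis family by default, or pool all p values for the stricter
    study-wide variant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError(f"p values outside [0, 1] in family {family!r}")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def save_heatmap(matrix: pd.DataFrame, path, reorder: bool = False,
                 cmap: str = "RdBu_r", vmin: float = -1.0, vmax: float = 1.0) -> None:
    """Plain heatmap export of a correlation/effect matrix to an image file.

    The values, not the styling, are the contract; ``reorder`` applies
    :func:`cluster_order` to rows and columns of a square matrix.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if reorder:
        order = cluster_order(matrix)
        matrix = matrix.loc[order, order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * matrix.shape[1] + 2), max(3, 0.3 * matrix.shape[0] + 1))
    )
    im = ax.imshow(matrix.to_numpy(dtype=float), cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(matrix.shape[1]), labels=matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), labels=matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class TestLedger:
    """Counts of hypothesis tests per named analysis family."""

    families: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.families.values())


@dataclass(frozen=True)
class LedgerConfig:
    """Enumerates the analyses whose test counts the ledger derives.

    The replication layout uses a 32-entry ROI list for the phenotypic
    regressions but 30 ROI variance-decomposition targets; the two lists are
    therefore configured independently.
    """

    rois_phenotypic: tuple[str, ...] = ()
    rois_univariate: tuple[str, ...] = ()
    rois_bivariate: tuple[str, ...] = ()
    behaviors: tuple[str, ...] = ()
    univariate_tests: tuple[str, ...] = ("A", "C", "AC")
    univariate_variants: tuple[str, ...] = ("no_tbv", "tbv")
    bivariate_components: tuple[str, ...] = ("A", "C", "E")
    include_behavior_univariate: bool = True


def build_ledger(config: LedgerConfig) -> TestLedger:
    """Derive the hypothesis-test ledger purely from configuration counts."""
    families = {
        "phenotypic": len(config.rois_phenotypic) * len(config.behaviors),
        "behavioral_univariate": (
            len(config.behaviors) * len(config.univariate_tests)
            if config.include_behavior_univariate
            else 0
        ),
        "roi_univariate": (
            len(config.rois_univariate)
            * len(config.univariate_tests)
            * len(config.univariate_variants)
        ),
        "bivariate": (
            len(config.rois_bivariate)
            * len(config.behaviors)
            * len(config.bivariate_components)
        ),
    }
    return TestLedger(families={k: v for k, v in families.items() if v})


def replication_ledger_config() -> LedgerConfig:
    """The study-shaped ledger: 288 + 27 + 180 + 810 = 1305 tests.

    The phenotypic stage screens 32 ROI measures against 9 behaviors; the
    genetic stages decompose 30 ROI volumes (univariate, with and without a
    TBV covariate, three submodel tests each) and 30 ROI x 9 behavior pairs
    (three covariance-path tests each).
    """
    from .fixtures import behavior_names, roi_names

    rois30 = tuple(roi_names())
    lobes = ("Cbm_Anterior_Lobe", "Cbm_Superior_Posterior_Lobe",
             "Cbm_Inferior_Posterior_Lobe")
    # 27 parcellated subsegments + 3 derived lobes + 2 hemispheric cortices
    subsegments = tuple(r for r in rois30
                        if r not in ("Left_Cerebellum_Cortex",
                                     "Right_Cerebellum_Cortex", "Cbm_Vermis"))
    rois32 = subsegments + lobes + ("Left_Cerebellum_Cortex", "Right_Cerebellum_Cortex")
    return LedgerConfig(
        rois_phenotypic=rois32,
        rois_univariate=rois30,
        rois_bivariate=rois30,
        behaviors=tuple(behavior_names()),
    )
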
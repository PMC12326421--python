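"""Reformat individual-wise cohorts into family-wise records.

The likelihood engines consume :class:`FamilyRecord` objects: one stacked
phenotype vector per family together with the pairwise relatedness
coefficients that determine how the A and C variance components propagate
between members (1.0 between MZ co-twins, 0.5 between DZ twins and full
siblings for A; 1.0 within a family for C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ID_COLUMNS, _relatedness_a

__all__ = ["RelatednessCoefficients", "FamilyRecord", "to_family_records", "records_to_frame"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RelatednessCoefficients:
    """Pairwise A- and C-coefficient matrices for one family's m members."""

    rA: np.ndarray
    rC: np.ndarray

    def __post_init__(self) -> None:
        for mat in (self.rA, self.rC):
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise ValueError("relatedness matrices must be square")
            if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 1.0):
                raise ValueError("relatedness matrices must be symmetric with unit diagonal")


@dataclass(frozen=True)
class FamilyRecord:
    """One family's data, the unit of FIML analysis.

    ``y`` stacks phenotypes trait-major (all members' trait 1, then trait 2,
    ...), length m*t, with NaN marking missing entries. ``X`` is the m x p
    mean-model design (intercept first) shared across traits.
    """

    family_id: str
    person_ids: tuple[str, ...]
    y: np.ndarray
    X: np.ndarray
    relatedness: RelatednessCoefficients
    trait_names: tuple[str, ...]
    covariate_names: tuple[str, ...]

    @property
    def n_members(self) -> int:
        return len(self.person_ids)


def to_family_records(
    cohort: pd.DataFrame,
    traits: list[str],
    covariates: tuple[str, ...] = ("sex", "age"),
) -> list[FamilyRecord]:
    """Group a cohort into family records for the given traits and covariates.

    Age is centered at the sample mean (conditioning only; it moves the
    intercept, not the variance components). Members missing any covariate
    contribute no phenotypes for these models — their phenotype entries are
    set to missing and the count is logged — because the FIML mean model
    needs a complete covariate row for every modeled observation.
    """
    for label in list(traits) + list(covariates):
        if label not in cohort.columns:
            raise KeyError(f"unknown trait/covariate column {label!r}")

    work = cohort.reset_index(drop=True).copy()
    if "age" in covariates:
        work["age"] = work["age"] - work["age"].mean()

    cov_block = work[list(covariates)].to_numpy(dtype=float)
    bad_cov = np.isnan(cov_block).any(axis=1)
    if bad_cov.any():
        logger.info("dropping phenotypes for %d member(s) with missing covariates", bad_cov.sum())

    records = []
    for fid, grp in work.groupby("family_id", sort=True):
        grp = grp.sort_values("person_id")
        rels = tuple(grp["relationship"])
        m = len(grp)
        x = np.column_stack([np.ones(m), grp[list(covariates)].to_numpy(dtype=float)])
        y = grp[list(traits)].to_numpy(dtype=float).T.reshape(-1).copy()  # trait-major
        member_bad = np.isnan(x).any(axis=1)
        if member_bad.any():
            y[np.tile(member_bad, len(traits))] = np.nan
            x[member_bad] = 0.0  # masked; never multiplies an observed entry
        records.append(
            FamilyRecord(
                family_id=str(fid),
                person_ids=tuple(grp["person_id"]),
                y=y,
                X=x,
                relatedness=RelatednessCoefficients(
                    rA=_relatedness_a(rels), rC=np.ones((m, m))
                ),
                trait_names=tuple(traits),
                covariate_names=("intercept",) + tuple(covariates),
            )
        )
    return records


def records_to_frame(records: list[FamilyRecord]) -> pd.DataFrame:
    """Flatten family records back to an individual-wise table (diagnostics,
    round-trip checks). Covariates are returned as modeled (age centered)."""
    rows = []
    for rec in records:
        t = len(rec.trait_names)
        m = rec.n_members
        y = rec.y.reshape(t, m)
        for j, pid in enumerate(rec.person_ids):
            row: dict = {"person_id": pid, "family_id": rec.family_id}
            for c, name in enumerate(rec.covariate_names[1:], start=1):
                row[name] = rec.X[j, c]
            for i, trait in enumerate(rec.trait_names):
                row[trait] = y[i, j]
            rows.append(row)
    return pd.DataFrame(rows)
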
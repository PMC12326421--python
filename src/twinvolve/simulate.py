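"""Synthetic twin-family cohort generation with known ACE structure.

The generator produces individual-wise records shaped like an extended twin
design: monozygotic (MZ) twin pairs, dizygotic (DZ) twin pairs, optional
extra full siblings attached to twin families, and unrelated singletons.
Phenotypes follow the classical ACE decomposition: for trait *t* and person
*i*,

    y_it = mean_t + sum_k beta_tk x_ik + sd_t * (a_t G + c_t S + e_t U)

with ``a_t = sqrt(a2)`` etc., where the additive-genetic score G correlates
1.0 within MZ pairs and 0.5 within DZ/sibling pairs, the shared-environment
score S is identical within a family, and the unique-environment score U is
independent. Cross-trait structure enters through component-wise latent
correlation matrices (rA, rC, rE), giving each family's latent scores the
covariance ``K_component (x) R_component`` (members x traits).

With all covariate slopes zero (the default), ``total_sd`` is the marginal
phenotypic SD, so sample moments match the calibration scale directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortDesign",
    "TraitSpec",
    "CrossTraitSpec",
    "RELATIONSHIPS",
    "ID_COLUMNS",
    "generate_cohort",
    "simulate_phenotypes",
    "write_cohort",
    "read_cohort",
    "component_correlation_matrices",
    "cross_spec_for_phenotypic_r",
]

RELATIONSHIPS = ("MZ_twin", "DZ_twin", "sibling", "singleton")

#: Leading identifier/covariate columns of the cohort table, in file order.
ID_COLUMNS = ("person_id", "family_id", "relationship", "sex", "age")


class ConfigurationError(ValueError):
    """Invalid design, trait, or cross-trait configuration."""


@dataclass(frozen=True)
class CohortDesign:
    """Demographic layout of a simulated cohort.

    Defaults reproduce the study sample: 121 MZ pairs, 67 DZ pairs and 556
    singletons (932 people), 45% male, ages drawn from a normal(28.8, 3.6)
    truncated to the young-adult range 22-37 years. ``n_extra_siblings``
    attaches that many additional full siblings to every twin family,
    exposing the extended-twin-design path without guessing a particular
    family-configuration mix.
    """

    n_mz_pairs: int = 121
    n_dz_pairs: int = 67
    n_singletons: int = 556
    sex_ratio: float = 0.45
    age_mean: float = 28.8
    age_sd: float = 3.6
    age_range: tuple[float, float] = (22.0, 37.0)
    n_extra_siblings: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mz_pairs", "n_dz_pairs", "n_singletons", "n_extra_siblings"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must be in [0, 1]")
        if self.age_sd < 0:
            raise ConfigurationError("age_sd must be >= 0")

    @property
    def n_individuals(self) -> int:
        per_twin_family = 2 + self.n_extra_siblings
        return (self.n_mz_pairs + self.n_dz_pairs) * per_twin_family + self.n_singletons


@dataclass(frozen=True)
class TraitSpec:
    """Generating model for one trait.

    ``a2 + c2 + e2`` must equal 1 (to 1e-12); ``total_sd`` is the SD of the
    covariate-free part of the phenotype, in trait units. ``covariate_betas``
    maps covariate names (``sex``, ``age``, or a previously generated trait
    such as ``tbv``) to slopes in trait units per covariate unit.
    ``missing_rate`` applies missing-completely-at-random dropout.
    """

    name: str
    mean: float
    total_sd: float
    a2: float
    c2: float
    e2: float
    covariate_betas: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.a2, self.c2, self.e2):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{self.name}: proportions must be in [0, 1]")
        if abs(self.a2 + self.c2 + self.e2 - 1.0) > 1e-12:
            raise ConfigurationError(
                f"{self.name}: a2 + c2 + e2 = {self.a2 + self.c2 + self.e2!r}, must be 1"
            )
        if self.total_sd <= 0:
            raise ConfigurationError(f"{self.name}: total_sd must be > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError(f"{self.name}: missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class CrossTraitSpec:
    """Latent component correlations between one pair of traits."""

    trait_x: str
    trait_y: str
    rA: float = 0.0
    rC: float = 0.0
    rE: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.rA, self.rC, self.rE):
            if not -1.0 <= r <= 1.0:
                raise ConfigurationError("component correlations must be in [-1, 1]")


def component_correlation_matrices(
    traits: list[TraitSpec], cross: list[CrossTraitSpec]
) -> dict[str, np.ndarray]:
    """Assemble and validate the T x T latent correlation matrices rA/rC/rE.

    Raises ``ConfigurationError`` if any assembled matrix is not positive
    semi-definite (tolerance 1e-8 on the smallest eigenvalue).
    """
    names = [t.name for t in traits]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate trait names")
    index = {n: i for i, n in enumerate(names)}
    mats = {comp: np.eye(len(traits)) for comp in ("rA", "rC", "rE")}
    for spec in cross:
        for n in (spec.trait_x, spec.trait_y):
            if n not in index:
                raise ConfigurationError(f"cross-trait spec names unknown trait {n!r}")
        i, j = index[spec.trait_x], index[spec.trait_y]
        if i == j:
            raise ConfigurationError("cross-trait spec must name two distinct traits")
        for comp, r in (("rA", spec.rA), ("rC", spec.rC), ("rE", spec.rE)):
            mats[comp][i, j] = mats[comp][j, i] = r
    for comp, mat in mats.items():
        if np.linalg.eigvalsh(mat).min() < -1e-8:
            raise ConfigurationError(f"{comp} correlation matrix is not positive semi-definite")
    return mats


def cross_spec_for_phenotypic_r(
    trait_x: TraitSpec, trait_y: TraitSpec, r_phenotypic: float
) -> CrossTraitSpec:
    """Cross-trait spec with equal component correlations hitting a target
    phenotypic correlation.

    Under the generating model the phenotypic correlation decomposes as
    ``sqrt(a2_x a2_y) rA + sqrt(c2_x c2_y) rC + sqrt(e2_x e2_y) rE``; setting
    rA = rC = rE = r0 gives ``r0 = r_ph / sum_k sqrt(k2_x k2_y)``.
    """
    weight = (
        np.sqrt(trait_x.a2 * trait_y.a2)
        + np.sqrt(trait_x.c2 * trait_y.c2)
        + np.sqrt(trait_x.e2 * trait_y.e2)
    )
    r0 = r_phenotypic / weight
    if abs(r0) > 1:
        raise ConfigurationError(
            f"phenotypic correlation {r_phenotypic} unreachable for these proportions"
        )
    return CrossTraitSpec(trait_x.name, trait_y.name, rA=r0, rC=r0, rE=r0)


def _truncated_normal(rng, mean, sd, low, high, size):
    from scipy.stats import truncnorm

    if sd == 0:
        return np.full(size, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Sample the demographic skeleton of a cohort (no phenotypes).

    Returns a frame with columns ``person_id, family_id, relationship, sex,
    age``, one row per person. MZ co-twins share sex; twins share age;
    extra siblings get independently drawn sex and age. Deterministic for a
    given (design, seed).
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    fam = 0

    def new_family() -> str:
        nonlocal fam
        fam += 1
        return f"F{fam:05d}"

    for kind, n_pairs in (("MZ_twin", design.n_mz_pairs), ("DZ_twin", design.n_dz_pairs)):
        for _ in range(n_pairs):
            fid = new_family()
            age = _truncated_normal(rng, design.age_mean, design.age_sd, *design.age_range, 1)[0]
            if kind == "MZ_twin":
                sex = int(rng.random() < design.sex_ratio)
                sexes = (sex, sex)
            else:
                sexes = tuple(int(rng.random() < design.sex_ratio) for _ in range(2))
            for k, sex in enumerate(sexes, start=1):
                rows.append((f"{fid}_{k:02d}", fid, kind, sex, age))
            for k in range(design.n_extra_siblings):
                sib_age = _truncated_normal(
                    rng, design.age_mean, design.age_sd, *design.age_range, 1
                )[0]
                sib_sex = int(rng.random() < design.sex_ratio)
                rows.append((f"{fid}_{k + 3:02d}", fid, "sibling", sib_sex, sib_age))
    for _ in range(design.n_singletons):
        fid = new_family()
        age = _truncated_normal(rng, design.age_mean, design.age_sd, *design.age_range, 1)[0]
        sex = int(rng.random() < design.sex_ratio)
        rows.append((f"{fid}_01", fid, "singleton", sex, age))

    return pd.DataFrame(rows, columns=list(ID_COLUMNS))


def _relatedness_a(relationships: tuple[str, ...]) -> np.ndarray:
    """Additive-genetic relatedness matrix for one family's members."""
    m = len(relationships)
    k = np.full((m, m), 0.5)
    np.fill_diagonal(k, 1.0)
    for i in range(m):
        for j in range(m):
            if i != j and relationships[i] == "MZ_twin" and relationships[j] == "MZ_twin":
                k[i, j] = 1.0
    if m == 1:
        k[:] = 1.0
    return k


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    w, u = np.linalg.eigh(mat)
    w = np.clip(w, 0.0, None)
    return u * np.sqrt(w) @ u.T


def simulate_phenotypes(
    cohort: pd.DataFrame,
    traits: list[TraitSpec],
    cross: list[CrossTraitSpec] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill phenotype columns on a copy of the cohort frame.

    Latent A/C/E scores are sampled family-block-wise with covariance
    ``K_comp (x) R_comp`` (members x traits) using symmetric matrix square
    roots, which handles singular relatedness patterns (MZ pairs) exactly.
    Traits are generated in list order, so a trait used as a covariate of a
    later trait (e.g. ``tbv``) must precede it.
    """
    cross = list(cross or [])
    rmats = component_correlation_matrices(traits, cross)
    n_traits = len(traits)
    rng = np.random.default_rng(seed)
    out = cohort.reset_index(drop=True).copy()
    n = len(out)

    # latent scores per person x trait, one array per variance component
    scores = {comp: np.empty((n, n_traits)) for comp in ("rA", "rC", "rE")}
    l_r = {comp: _psd_sqrt(rmats[comp]) for comp in rmats}

    fam_groups: dict[tuple[str, ...], list[np.ndarray]] = {}
    for _, idx in out.groupby("family_id", sort=True).indices.items():
        order = idx[np.argsort(out.loc[idx, "person_id"].to_numpy())]
        rels = tuple(out.loc[order, "relationship"])
        fam_groups.setdefault(rels, []).append(order)

    # deterministic iteration order over patterns
    for rels in sorted(fam_groups):
        members = np.stack(fam_groups[rels])  # (g, m) row indices
        g, m = members.shape
        l_k = {
            "rA": _psd_sqrt(_relatedness_a(rels)),
            "rC": np.ones((m, m)) / np.sqrt(m),  # (J/sqrt(m))^2 = J
            "rE": np.eye(m),
        }
        for comp in ("rA", "rC", "rE"):
            z = rng.standard_normal((g, m, n_traits))
            s = np.einsum("ij,gjt->git", l_k[comp], z)
            s = np.einsum("git,ut->giu", s, l_r[comp])
            scores[comp][members.reshape(-1)] = s.reshape(g * m, n_traits)

    for t_idx, spec in enumerate(traits):
        latent = (
            np.sqrt(spec.a2) * scores["rA"][:, t_idx]
            + np.sqrt(spec.c2) * scores["rC"][:, t_idx]
            + np.sqrt(spec.e2) * scores["rE"][:, t_idx]
        )
        values = spec.mean + spec.total_sd * latent
        for cov, beta in spec.covariate_betas.items():
            if cov not in out.columns:
                raise ConfigurationError(
                    f"{spec.name}: covariate {cov!r} not available (order traits so "
                    "generated covariates come first)"
                )
            values = values + beta * out[cov].to_numpy(dtype=float)
        if spec.missing_rate > 0:
            mask = rng.random(n) < spec.missing_rate
            values = np.where(mask, np.nan, values)
        out[spec.name] = values

    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to CSV (UTF-8, header, empty field = missing).

    Column order is ``person_id, family_id, relationship, sex, age, tbv,
    <traits...>``; a ``tbv`` column is emitted (empty if never simulated) so
    files are structurally uniform. Byte-identical for identical input.
    """
    df = cohort.copy()
    if "tbv" not in df.columns:
        df["tbv"] = np.nan
    traits = [c for c in df.columns if c not in ID_COLUMNS and c != "tbv"]
    df = df[list(ID_COLUMNS) + ["tbv"] + traits]
    df.to_csv(path, index=False, lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Raises ``ValueError`` naming the offending row for duplicate person ids
    or unknown relationship codes; warns (without rejecting) on MZ co-twins
    of differing sex. A twin whose co-twin row is absent is accepted and is
    simply an informative singleton for the likelihood.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in ID_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort file lacks required columns {missing_cols}")
    dup = df["person_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 2  # 1-based, plus header
        raise ValueError(f"duplicate person_id {df['person_id'][dup].iloc[0]!r} at line {row}")
    bad = ~df["relationship"].isin(RELATIONSHIPS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(
            f"unknown relationship {df['relationship'][bad].iloc[0]!r} at line {row}"
        )
    for fid, grp in df[df.relationship == "MZ_twin"].groupby("family_id"):
        if grp["sex"].nunique() > 1:
            warnings.warn(f"MZ co-twins in family {fid} differ in sex", stacklevel=2)
    return df
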
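"""Access to the calibration table shipped with the package.

``fixtures/paper_tables.csv`` transcribes, in long form, the published
summary statistics the synthetic cohorts are calibrated against: the
MZ/DZ/singleton demographic mix, the behavioral score scales, the cerebellar
ROI volume scales (mm^3), the univariate ACE variance proportions for
behaviors (with 95% CI bounds) and for ROIs (with and without a total brain
volume covariate), and two reported cross-trait phenotypic correlations.

Printed proportions carry two-decimal rounding, so a row's a2 + c2 + e2 can
be 0.99 or 1.01; :func:`generating_proportions` renormalizes them to sum to
one, which is what a generating model requires.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

__all__ = [
    "load_paper_tables",
    "cohort_design_values",
    "trait_scale",
    "generating_proportions",
    "reported_correlation",
    "behavior_names",
    "roi_names",
]


@lru_cache(maxsize=1)
def load_paper_tables() -> pd.DataFrame:
    """Return the calibration table as a tidy frame (section, name, field, value)."""
    ref = resources.files("twinvolve") / "fixtures" / "paper_tables.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype={"section": str, "name": str, "field": str})
    df["value"] = df["value"].astype(float)
    return df


def _lookup(section: str, name: str, field: str) -> float:
    df = load_paper_tables()
    hit = df[(df.section == section) & (df.name == name) & (df.field == field)]
    if len(hit) != 1:
        raise KeyError(f"no unique fixture entry for ({section}, {name}, {field})")
    return float(hit["value"].iloc[0])


def cohort_design_values() -> dict[str, float]:
    """Demographic design values: pair counts, age distribution, sex ratio."""
    df = load_paper_tables()
    sub = df[df.section == "cohort"]
    return dict(zip(sub["field"], sub["value"]))

def trait_scale(name: str) -> tuple[float, float]:
    """(mean, sd) on the published scale for a behavior or ROI volume."""
    df = load_paper_tables()
    for section in ("behavior", "roi_volume"):
        sub = df[(df.section == section) & (df.name == name)]
        if len(sub):
            vals = dict(zip(sub["field"], sub["value"]))
            return vals["mean"], vals["sd"]
    raise KeyError(f"unknown trait {name!r}")


def generating_proportions(name: str, with_tbv: bool = False) -> tuple[float, float, float]:
    """Renormalized (a2, c2, e2) generating proportions for a trait.

    Behaviors come from the behavioral variance-components table; ROIs from
    the ROI table, where ``with_tbv`` selects the TBV-covaried column block.
    """
    df = load_paper_tables()
    suffix = "_tbv" if with_tbv else ""
    for section in ("behavior_ace", "roi_ace"):
        sub = df[(df.section == section) & (df.name == name)]
        if len(sub):
            vals = dict(zip(sub["field"], sub["value"]))
            try:
                raw = (vals["a2" + suffix], vals["c2" + suffix], vals["e2" + suffix])
            except KeyError:
                raise KeyError(f"no {'TBV' if with_tbv else 'plain'} proportions for {name!r}")
            total = sum(raw)
            return tuple(v / total for v in raw)  # type: ignore[return-value]
    raise KeyError(f"unknown trait {name!r}")


def reported_correlation(pair: str) -> float:
    """A published cross-trait phenotypic correlation, by fixture pair label."""
    return _lookup("correlation", pair, "phenotypic_r")


def behavior_names() -> list[str]:
    df = load_paper_tables()
    return list(dict.fromkeys(df[df.section == "behavior"]["name"]))


def roi_names() -> list[str]:
    df = load_paper_tables()
    return list(dict.fromkeys(df[df.section == "roi_volume"]["name"]))
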
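"""Run configuration: YAML parsing and seed-substream derivation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import CohortDesign, ConfigurationError, CrossTraitSpec, TraitSpec

__all__ = ["RunConfig", "load_run_config", "child_seed", "SUBSTREAMS"]

#: Named randomness substreams, all derived from the single root seed.
SUBSTREAMS = {"cohort": 0, "phenotypes": 1, "starts": 2, "permutations": 3}


def child_seed(root_seed: int, stream: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the root."""
    return (int(root_seed) * 1_000_003 + SUBSTREAMS[stream]) % (2**31)


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    cohort_file: Path | None = None
    design: CohortDesign | None = None
    traits: list[TraitSpec] = field(default_factory=list)
    cross: list[CrossTraitSpec] = field(default_factory=list)
    rois: list[str] = field(default_factory=list)
    behaviors: list[str] = field(default_factory=list)
    with_tbv: bool = False
    fdr_scope: str = "per_family"  # or "global"
    compute_ci: bool = False
    n_starts: int = 5

    def __post_init__(self) -> None:
        if self.cohort_file is None and self.design is None:
            raise ConfigurationError("config needs either a cohort file or a design")
        if self.cohort_file is None and self.seed is None:
            raise ConfigurationError("seed is mandatory when simulating")
        if self.fdr_scope not in ("per_family", "global"):
            raise ConfigurationError("fdr_scope must be 'per_family' or 'global'")


def _trait_from_mapping(entry: dict) -> TraitSpec:
    return TraitSpec(
        name=entry["name"],
        mean=float(entry.get("mean", 0.0)),
        total_sd=float(entry.get("sd", entry.get("total_sd", 1.0))),
        a2=float(entry["a2"]),
        c2=float(entry["c2"]),
        e2=float(entry["e2"]),
        covariate_betas={k: float(v) for k, v in entry.get("covariate_betas", {}).items()},
        missing_rate=float(entry.get("missing_rate", 0.0)),
    )


def _cross_from_mapping(entry: dict, traits: list[TraitSpec]) -> CrossTraitSpec:
    if "phenotypic_r" in entry:
        from .simulate import cross_spec_for_phenotypic_r

        by_name = {t.name: t for t in traits}
        return cross_spec_for_phenotypic_r(
            by_name[entry["x"]], by_name[entry["y"]], float(entry["phenotypic_r"])
        )
    return CrossTraitSpec(
        trait_x=entry["x"],
        trait_y=entry["y"],
        rA=float(entry.get("rA", 0.0)),
        rC=float(entry.get("rC", 0.0)),
        rE=float(entry.get("rE", 0.0)),
    )


def load_run_config(path) -> RunConfig:
    """Parse a YAML run configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    traits = [_trait_from_mapping(e) for e in raw.get("traits", [])]
    design = CohortDesign(**raw["design"]) if "design" in raw else None
    return RunConfig(
        seed=int(raw["seed"]),
        output_dir=Path(raw.get("output_dir", "twinvolve_out")),
        cohort_file=Path(raw["cohort_file"]) if "cohort_file" in raw else None,
        design=design,
        traits=traits,
        cross=[_cross_from_mapping(e, traits) for e in raw.get("cross", [])],
        rois=list(raw.get("rois", [])),
        behaviors=list(raw.get("behaviors", [])),
        with_tbv=bool(raw.get("with_tbv", False)),
        fdr_scope=str(raw.get("fdr_scope", "per_family")),
        compute_ci=bool(raw.get("ci", False)),
        n_starts=int(raw.get("n_starts", 5)),
    )
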
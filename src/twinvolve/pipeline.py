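"""End-to-end orchestration: simulate/load -> associate -> decompose -> correct.

Stages run in a fixed order with all randomness derived from the single root
seed via named substreams, so re-running an identical configuration
reproduces every output byte-for-byte. Logs go to stderr via ``logging``;
results only ever go to files under the configured output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .ace_biv import fit_bivariate, test_cov_path
from .ace_uni import MODELS, fit_ace, lrt, profile_ci
from .assoc import (
    LedgerConfig,
    build_ledger,
    correlation_matrix,
    fdr_adjust,
    fit_brain_behavior,
)
from .config import RunConfig, child_seed
from .reshape import to_family_records
from .simulate import generate_cohort, read_cohort, simulate_phenotypes, write_cohort

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are left in place."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", stage, dt)
                return False
            raise StageError(stage, exc) from exc

    return _Timer()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a manifest dict (also written to disk)."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    with _timed("cohort"):
        if config.cohort_file is not None:
            cohort = read_cohort(config.cohort_file)
        else:
            cohort = generate_cohort(config.design, child_seed(config.seed, "cohort"))
            if config.traits:
                cohort = simulate_phenotypes(
                    cohort, config.traits, config.cross,
                    seed=child_seed(config.seed, "phenotypes"),
                )
        write_cohort(cohort, out / "cohort.csv")
        manifest["stages"]["cohort"] = {"n_individuals": len(cohort)}

    covariates = ["sex", "age"] + (["tbv"] if config.with_tbv else [])
    rois, behaviors = config.rois, config.behaviors
    all_p: list[float] = []
    frames: dict[str, pd.DataFrame] = {}

    with _timed("assoc"):
        variables = [v for v in behaviors + rois if v in cohort.columns]
        if variables:
            correlation_matrix(cohort, variables).to_csv(out / "correlations.csv")
        rows = []
        assoc_covs = tuple(c for c in ("age", "sex", "tbv")
                           if c in cohort.columns and (c != "tbv" or config.with_tbv))
        for roi in rois:
            for beh in behaviors:
                res = fit_brain_behavior(cohort, roi, beh, covariates=assoc_covs)
                rows.append(asdict(res))
        assoc_df = pd.DataFrame(rows)
        if len(assoc_df):
            assoc_df["q_value"] = fdr_adjust(assoc_df["p_value"], "phenotypic")
            all_p.extend(assoc_df["p_value"])
        frames["assoc"] = assoc_df
        manifest["stages"]["assoc"] = {"n_tests": len(assoc_df)}

    seed_starts = child_seed(config.seed, "starts")
    with _timed("ace_uni"):
        rows = []
        variants = [("no_tbv", ("sex", "age"))]
        if config.with_tbv:
            variants.append(("tbv", ("sex", "age", "tbv")))
        for trait in behaviors + rois:
            trait_variants = variants if trait in rois else [variants[0]]
            for variant, covs in trait_variants:
                records = to_family_records(cohort, [trait], covariates=covs)
                fits = {m: fit_ace(records, model=m, n_starts=config.n_starts,
                                   seed=seed_starts) for m in MODELS}
                tests = {t.name: t for t in (
                    lrt(fits["ACE"], fits["CE"]),
                    lrt(fits["ACE"], fits["AE"]),
                    lrt(fits["ACE"], fits["E"]),
                )}
                row = {
                    "trait": trait,
                    "variant": variant,
                    "a2": fits["ACE"].a2,
                    "c2": fits["ACE"].c2,
                    "e2": fits["ACE"].e2,
                    "minus2lnl": fits["ACE"].minus2lnl,
                    "converged": fits["ACE"].converged,
                    "p.A": tests["A"].p_value,
                    "p.C": tests["C"].p_value,
                    "p.AC": tests["AC"].p_value,
                }
                if config.compute_ci:
                    for q in ("a2", "c2", "e2"):
                        ci = profile_ci(records, fits["ACE"], quantity=q)
                        row[f"{q}_lo"], row[f"{q}_hi"] = ci.lower, ci.upper
                rows.append(row)
        uni_df = pd.DataFrame(rows)
        if len(uni_df):
            for col, fam in (("p.A", "uni_A"), ("p.C", "uni_C"), ("p.AC", "uni_AC")):
                uni_df["q" + col[1:]] = fdr_adjust(uni_df[col], fam)
                all_p.extend(uni_df[col])
        frames["ace_uni"] = uni_df
        manifest["stages"]["ace_uni"] = {"n_fits": len(uni_df)}

    with _timed("ace_biv"):
        rows = []
        for roi in rois:
            for beh in behaviors:
                records = to_family_records(cohort, [roi, beh],
                                            covariates=tuple(covariates[:2]))
                full = fit_bivariate(records, n_starts=config.n_starts,
                                     seed=seed_starts)
                row = {
                    "roi": roi,
                    "behavior": beh,
                    "rG": full.rG.value, "rG_defined": full.rG.defined,
                    "rC": full.rC.value, "rC_defined": full.rC.defined,
                    "rE": full.rE.value, "rE_defined": full.rE.defined,
                    "pcorA": full.pcorA, "pcorC": full.pcorC, "pcorE": full.pcorE,
                    "phenotypic_r": full.phenotypic_correlation,
                }
                for comp in ("A", "C", "E"):
                    res = test_cov_path(records, comp, full=full,
                                        n_starts=config.n_starts, seed=seed_starts)
                    row[f"p.{comp}"] = res.p_value
                rows.append(row)
        biv_df = pd.DataFrame(rows)
        if len(biv_df):
            for comp in ("A", "C", "E"):
                biv_df[f"q.{comp}"] = fdr_adjust(biv_df[f"p.{comp}"], f"biv_{comp}")
                all_p.extend(biv_df[f"p.{comp}"])
        frames["ace_biv"] = biv_df
        manifest["stages"]["ace_biv"] = {"n_pairs": len(biv_df)}

    with _timed("ledger"):
        ledger = build_ledger(
            LedgerConfig(
                rois_phenotypic=tuple(rois),
                rois_univariate=tuple(rois),
                rois_bivariate=tuple(rois),
                behaviors=tuple(behaviors),
                univariate_variants=("no_tbv", "tbv") if config.with_tbv else ("no_tbv",),
            )
        )
        (out / "ledger.json").write_text(
            json.dumps({"families": ledger.families, "total": ledger.total}, indent=2)
        )
        manifest["stages"]["ledger"] = {"total": ledger.total}

    if config.fdr_scope == "global" and all_p:
        q_global = fdr_adjust(np.asarray(all_p), "global")
        offset = 0
        for name in ("assoc", "ace_uni", "ace_biv"):
            df = frames[name]
            if not len(df):
                continue
            p_cols = [c for c in df.columns if c == "p_value" or c.startswith("p.")]
            for col in p_cols:
                qcol = "q_global" if col == "p_value" else "q_global" + col[1:]
                df[qcol] = q_global[offset:offset + len(df)]
                offset += len(df)

    for name, df in frames.items():
        df.to_csv(out / f"{name}.csv", index=False)

    manifest["config_hash"] = hashlib.sha256(
        repr(sorted(manifest["stages"].items())).encode()
        + str(config).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
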
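"""End-to-end orchestration: simulate -> build cohort -> screen -> tree -> validate.

`run_pipeline` executes the whole analysis on a synthetic cohort (or a
pre-existing EMR bundle) and writes a reproducible report bundle:
cohort-flow JSON, screen CSV, tree JSON + text rendering, holdout
validation CSV, and a manifest capturing the full configuration and
seeds.  Any stage failure aborts with the stage name; partial outputs
are removed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (DEFAULT_CODES, build_analysis_table, cohort_flow,
                     exposure_summary, select_eligible, temporal_holdout)
from .cta import fit_cta, render_tree, tree_to_dict, validate_holdout
from .io import read_emr_bundle, write_truth
from .metrics import metrics_from_counts, round_half_up
from .oda import screen_frame, univariable_screen
from .synthetic import PlantedTreeSpec, default_spec, generate_cohort, plant_outcome

log = logging.getLogger("odacta")

DEFAULT_PREDICTORS = [
    "exposure_days", "age_years", "prostate_disease", "nsaid",
    "hypertension", "depression",
]


@dataclass
class RunConfig:
    outdir: str = "odacta_run"
    bundle: str | None = None          # read this bundle instead of simulating
    n_subjects: int = 5000
    exposure_fraction: float = 1.0
    outcome_kind: str = "PED"
    predictors: list[str] = field(default_factory=lambda: list(DEFAULT_PREDICTORS))
    alpha: float = 0.05
    screen_mode: str = "generalized"
    tree_mode: str = "greedy"
    min_leaf_frac: float = 0.10
    max_depth: int = 4
    pde5i_window_days: int = 90
    min_persistence_days: int = 90
    holdout_cutoff: str | None = None  # ISO date; None disables validation
    n_mc: int = 999
    seed: int = 0


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    try:
        if config.bundle:
            stage = "build-cohort"  # loading an existing bundle is input parsing
            records = read_emr_bundle(config.bundle)
        else:
            stage = "simulate"
            spec = default_spec(n_subjects=config.n_subjects,
                                exposure_fraction=config.exposure_fraction,
                                seed=config.seed)
            records = generate_cohort(spec, config.seed)
            planted = plant_outcome(records, PlantedTreeSpec(), config.seed)
            emit("truth.json", lambda p: write_truth(planted.truth_dict(), p))
        log.info("input: %d records", len(records))

        stage = "build-cohort"
        eligible = select_eligible(records)
        table = build_analysis_table(
            eligible, config.outcome_kind,
            pde5i_window_days=config.pde5i_window_days,
            min_persistence_days=config.min_persistence_days)
        flow = cohort_flow(records, [("eligible", eligible)])
        flow["analysis_rows"] = len(table)
        flow["cases"] = int(table["outcome"].sum())
        emit("cohort_flow.json",
             lambda p: p.write_text(json.dumps(flow, indent=2)))
        emit("analysis_table.csv", lambda p: table.to_csv(p, index=False))
        log.info("build-cohort: %s", flow)

        stage = "screen"
        results = univariable_screen(
            table, config.predictors, alpha=config.alpha,
            mode=config.screen_mode, n_mc=config.n_mc, seed=config.seed)
        emit("screen.csv", lambda p: screen_frame(results).to_csv(p, index=False))
        log.info("screen: %d significant predictors", len(results))

        stage = "fit-tree"
        model = fit_cta(table, config.predictors, alpha=config.alpha,
                        min_leaf_frac=config.min_leaf_frac,
                        max_depth=config.max_depth, mode=config.tree_mode,
                        n_mc=config.n_mc, seed=config.seed)
        emit("tree.json",
             lambda p: p.write_text(json.dumps(tree_to_dict(model), indent=2)))
        emit("tree.txt", lambda p: p.write_text(render_tree(model) + "\n"))
        log.info("fit-tree: model ESS %.1f%%", model.model_ess)

        validation = None
        if config.holdout_cutoff:
            stage = "validate"
            cutoff = dt.date.fromisoformat(config.holdout_cutoff)
            _, holdout_records = temporal_holdout(records, cutoff)
            holdout_eligible = select_eligible(holdout_records)
            htable = build_analysis_table(
                holdout_eligible, config.outcome_kind,
                pde5i_window_days=config.pde5i_window_days,
                min_persistence_days=config.min_persistence_days)
            v = validate_holdout(model, htable)
            validation = {
                "n": v["n"], "ess": v["ess"],
                "sensitivity": v["metrics"].sensitivity,
                "specificity": v["metrics"].specificity,
            }
            emit("validation.csv",
                 lambda p: pd.DataFrame([validation]).to_csv(p, index=False))

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "seed": config.seed,
        }
        emit("manifest.json", lambda p: p.write_text(json.dumps(manifest, indent=2)))
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc

    return {"flow": flow, "screen": results, "model": model,
            "validation": validation, "outdir": str(outdir)}


def naive_analysis(records, codes=DEFAULT_CODES) -> pd.DataFrame:
    """Exposed-vs-unexposed crude comparison in the printed-table layout.

    Exposure = any 5α-RI prescription; effects = presence of ED codes,
    PDE5I prescriptions, or low-libido codes anywhere in the record
    (deliberately naive: no chronology or history exclusions).
    """
    from .cohort import _class_dates, _code_dates
    from .metrics import Counts2x2
    exposed = [bool(exposure_summary(r.prescriptions)) for r in records]
    rows = []
    for label, has_effect in (
            ("erectile_dysfunction",
             lambda r: bool(_code_dates(r, "ed", codes))),
            ("pde5_inhibitor", lambda r: bool(_class_dates(r, "PDE5I"))),
            ("low_libido", lambda r: bool(_code_dates(r, "low_libido", codes)))):
        a = b = c = d = 0
        for r, e in zip(records, exposed):
            eff = has_effect(r)
            if e and eff:
                a += 1
            elif e:
                b += 1
            elif eff:
                c += 1
            else:
                d += 1
        t = Counts2x2(a, b, c, d)
        m = metrics_from_counts(t)
        rows.append({
            "effect": label, "a": a, "b": b, "c": c,
            "nnh": round_half_up(m.nnh, 1) if m.nnh is not None else None,
            "risk_ratio": round_half_up(m.risk_ratio, 3) if m.risk_ratio else None,
            "specificity": round_half_up(m.specificity, 1),
            "sensitivity": round_half_up(m.sensitivity, 1),
            "npv": round_half_up(m.npv, 1), "ppv": round_half_up(m.ppv, 1),
            "ess": round_half_up(m.ess, 1),
        })
    return pd.DataFrame(rows)
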
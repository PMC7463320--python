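"""End-to-end orchestration: data -> filter -> normalize -> score -> compare/ROC.

A run is described by a plain dict (usually loaded from YAML)::

    seed: 1
    design: paired            # or case_control
    simulate:                 # either this ...
      n_subjects: 150
      n_background_probes: 200
      effects: {cg06126421: -1.0}
    inputs:                   # ... or paths to real data
      beta: beta.tsv
      sheet: samples.tsv
      detection_p: detp.tsv   # optional
    preprocess:
      p_threshold: 0.01
      missing_threshold: 0.05
      skip_normalization: false
      n_categories: 6
      categories: cats.tsv    # optional manifest; hashed categories otherwise
    clocks:
      - coefficients: mrscore
        missing_policy: mean_impute
    compare: {strata: [overall, stage]}
    roc: {positive: tumor, ci_method: delong}

Scores are computed after normalization by default; set
``preprocess.skip_normalization`` to score the filtered matrix directly.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .clocks import compute_linear_score
from .containers import BetaMatrix, SampleSheet
from .discrimination import roc_auc, roc_to_dict
from .paired_stats import compare_by_stratum, results_to_frame
from .preprocess import filter_probes, quantile_normalize_stratified
from .simulate import SimulationConfig, default_probes, simulate_case_control, simulate_paired

log = logging.getLogger(__name__)


def _obtain_data(config: dict) -> tuple[BetaMatrix, SampleSheet]:
    design = config.get("design", "paired")
    if "inputs" in config:
        inp = config["inputs"]
        beta = mio.read_beta_matrix(
            inp["beta"],
            orientation=inp.get("orientation", "probes-in-rows"),
            detection_p_path=inp.get("detection_p"),
        )
        sheet = mio.read_sample_sheet(inp["sheet"])
        return beta, sheet
    sim = dict(config.get("simulate", {}))
    n_background = sim.pop("n_background_probes", 200)
    clock_probes = sim.pop("clock_probes", None)
    if clock_probes is None:
        clock_probes = mio.load_bundled_coefficients("mrscore").probes
    sim.setdefault("probes", default_probes(clock_probes, n_background))
    sim.setdefault("seed", config.get("seed", 0))
    sc = SimulationConfig(**sim)
    if design == "paired":
        return simulate_paired(sc)
    if design == "case_control":
        return simulate_case_control(sc)
    raise ValueError(f"unknown design {design!r}")


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Run the full analysis described by ``config``.

    Returns a dict with the beta matrix, sample sheet, filter report,
    score table, paired-comparison results and ROC results; writes TSV/JSON
    artifacts under ``outdir`` when given.
    """
    design = config.get("design", "paired")
    beta, sheet = _obtain_data(config)

    pp = config.get("preprocess", {})
    filtered, report = filter_probes(
        beta,
        p_threshold=pp.get("p_threshold", 0.01),
        missing_threshold=pp.get("missing_threshold", 0.05),
        mode=pp.get("mode", "mask_then_remove"),
    )
    if pp.get("skip_normalization", False):
        normalized = filtered
    else:
        cats = mio.read_category_map(pp["categories"]) if "categories" in pp else None
        normalized = quantile_normalize_stratified(
            filtered, cats=cats, n_categories=pp.get("n_categories", 6)
        )

    clock_specs = config.get("clocks", [{"coefficients": "mrscore"}])
    tables = [
        compute_linear_score(
            normalized,
            spec["coefficients"],
            missing_policy=spec.get("missing_policy", "mean_impute"),
        )
        for spec in clock_specs
    ]
    scores = pd.concat(tables, ignore_index=True)

    comparisons = []
    if design == "paired":
        for strata in config.get("compare", {}).get("strata", ["overall"]):
            comparisons.extend(compare_by_stratum(scores, sheet, strata=strata))

    roc_cfg = config.get("roc", {})
    positive = roc_cfg.get("positive", "tumor" if design == "paired" else "case")
    rocs = [
        roc_auc(scores, sheet, positive, ci_method=roc_cfg.get("ci_method", "delong"), clock=c)
        for c in scores["clock"].unique()
    ]

    results = {
        "beta": normalized,
        "sheet": sheet,
        "filter_report": report,
        "scores": scores,
        "comparisons": comparisons,
        "rocs": rocs,
    }
    if outdir is not None:
        _write_outputs(results, config, Path(outdir))
    return results


def _write_outputs(results: dict, config: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_beta_matrix(results["beta"], outdir / "normalized_beta.tsv")
    mio.write_sample_sheet(results["sheet"], outdir / "sample_sheet.tsv")
    mio.write_score_table(results["scores"], outdir / "scores.tsv")
    with open(outdir / "filter_report.json", "w") as fh:
        json.dump(results["filter_report"].to_dict(), fh, indent=2)
    if results["comparisons"]:
        results_to_frame(results["comparisons"]).to_csv(
            outdir / "comparisons.tsv", sep="\t", index=False
        )
    with open(outdir / "roc.json", "w") as fh:
        json.dump([roc_to_dict(r) for r in results["rocs"]], fh, indent=2)
    for r in results["rocs"]:
        pd.DataFrame(r.points, columns=["fpr", "tpr"]).to_csv(
            outdir / f"roc_curve_{r.clock}.tsv", sep="\t", index=False
        )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    log.info("pipeline outputs written to %s", outdir)
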
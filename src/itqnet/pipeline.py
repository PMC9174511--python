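"""End-to-end orchestration: cohort IO, staged analysis, run manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from itqnet import __version__
from itqnet.cfa import WlsCfa, build_standard_models, compare_models, fit_indices, fit_independence, fit_wls
from itqnet.constants import EXPOSURE_COLUMNS, IMPAIRMENT_ITEMS, SYMPTOM_ITEMS
from itqnet.datagen import SimulationConfig, default_config, generate_cohort
from itqnet.epi import (
    MultinomialDiagnosisRegression,
    pearson_chi2,
    prevalence_ci,
)
from itqnet.network import EbicGlassoNetwork
from itqnet.polychoric import polychoric_matrix, wls_weight
from itqnet.scoring import ItqScorer, cronbach_alpha

log = logging.getLogger("itqnet")

ALL_STAGES = ("score", "cfa", "network", "epi")

_REQUIRED_COLUMNS = (
    ("gender", "nationality", "parental_education")
    + SYMPTOM_ITEMS
    + IMPAIRMENT_ITEMS
)


@dataclass
class PipelineConfig:
    """What to run and where to put it."""

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    stages: tuple = ALL_STAGES
    output_dir: str = "itqnet_output"
    seed: int = 0
    cfa_weight: str = "diag"
    network_gamma: float = 0.5
    network_correlation: str = "polychoric"

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if not self.stages:
            raise ValueError("select at least one stage")


def load_pipeline_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML or JSON file.

    Recognized keys mirror the dataclass fields; a ``simulation`` mapping is
    forwarded to :class:`~itqnet.datagen.SimulationConfig`.
    """
    import yaml

    with open(path) as fh:
        obj = yaml.safe_load(fh)
    if not isinstance(obj, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    sim = obj.pop("simulation", None)
    if sim is not None:
        obj["simulation"] = SimulationConfig(**sim)
    if "stages" in obj:
        obj["stages"] = tuple(obj["stages"])
    return PipelineConfig(**obj)


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by the generator schema.

    Checks column presence, item score ranges (0..4, missing allowed) and
    boolean exposure flags; raises with an itemized message on violations.
    """
    table = pd.read_csv(path)
    errors = []
    for col in _REQUIRED_COLUMNS:
        if col not in table.columns:
            errors.append(f"missing column: {col}")
    for col in SYMPTOM_ITEMS + IMPAIRMENT_ITEMS:
        if col not in table.columns:
            continue
        vals = table[col]
        bad = vals.dropna()
        offending = bad[(bad < 0) | (bad > 4) | (bad % 1 != 0)]
        for idx in offending.index[:5]:
            errors.append(f"row {idx}, column {col}: score {vals[idx]!r} outside 0..4")
    if errors:
        raise ValueError("cohort validation failed:\n  " + "\n  ".join(errors))
    for col in EXPOSURE_COLUMNS:
        if col in table.columns:
            table[col] = table[col].astype(bool)
    if "trauma_exposed" in table.columns:
        table["trauma_exposed"] = table["trauma_exposed"].astype(bool)
    return table


def _write_csv(df: pd.DataFrame, path: Path, **kwargs):
    df.to_csv(path, float_format="%.10g", **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the selected stages in order score -> cfa -> network -> epi.

    Returns the manifest dict (also written as ``manifest.json``); partial
    outputs are preserved and the failure recorded if a stage raises.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "options": {
            "cfa_weight": config.cfa_weight,
            "network_gamma": config.network_gamma,
            "network_correlation": config.network_correlation,
        },
        "stage_status": {},
        "outputs": [],
    }

    if config.input_path is not None:
        cohort = read_cohort_table(config.input_path)
        manifest["input"] = str(config.input_path)
    else:
        sim = config.simulation or default_config(seed=config.seed)
        cohort = generate_cohort(sim)
        manifest["input"] = "simulated"
        (out / "simulation_config.json").write_text(sim.to_json())
        _write_csv(cohort, out / "cohort.csv", index=False)
        manifest["outputs"] += ["simulation_config.json", "cohort.csv"]

    scored = ItqScorer().fit(cohort).transform(cohort)

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
            manifest["stage_status"][name] = "ok"
        except Exception as exc:  # noqa: BLE001 - manifest must record failures
            manifest["stage_status"][name] = f"failed: {exc}"
            log.exception("stage %s failed", name)
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    if "score" in config.stages:
        def _score():
            keep = ["subject_id"] if "subject_id" in scored.columns else []
            cols = keep + ["diagnosis", "ptsd_sum", "dso_sum"] + [
                c for c in scored.columns if c.startswith(("intentional_", "unintentional_", "any_"))
            ]
            _write_csv(scored[cols], out / "diagnoses.csv", index=False)
            valid = scored["diagnosis"].notna()
            n = int(valid.sum())
            rows = []
            for cat in ("PTSD", "cPTSD"):
                k = int((scored.loc[valid, "diagnosis"] == cat).sum())
                est = prevalence_ci(k, n)
                rows.append({"diagnosis": cat, "cases": k, "n": n,
                             "percent": est.point, "ci_low": est.ci_low,
                             "ci_high": est.ci_high})
            _write_csv(pd.DataFrame(rows), out / "prevalence.csv", index=False)
            for block, items in (("ptsd", SYMPTOM_ITEMS[:6]), ("dso", SYMPTOM_ITEMS[6:])):
                rel = cronbach_alpha(scored[list(items)].dropna().to_numpy())
                rows_alpha = {"subscale": block, "alpha": rel.alpha,
                              "n_items": rel.n_items, "n_subjects": rel.n_subjects}
                mode = "a" if block == "dso" else "w"
                header = block == "ptsd"
                pd.DataFrame([rows_alpha]).to_csv(
                    out / "reliability.csv", mode=mode, header=header, index=False
                )
            manifest["outputs"] += ["diagnoses.csv", "prevalence.csv", "reliability.csv"]
        stage("score", _score)

    items = scored[list(SYMPTOM_ITEMS)].dropna().astype(int)

    if "cfa" in config.stages:
        def _cfa():
            est = polychoric_matrix(items.to_numpy(), item_labels=list(SYMPTOM_ITEMS))
            if config.cfa_weight in ("full", "diag"):
                est.W, est.weight_meta = wls_weight(items.to_numpy(), seed=config.seed)
                np.savetxt(out / "wls_weight.csv", est.W, delimiter=",")
                (out / "wls_weight.meta.json").write_text(
                    json.dumps(est.weight_meta, indent=2)
                )
                manifest["outputs"] += ["wls_weight.csv", "wls_weight.meta.json"]
            baseline = fit_independence(est, weight=config.cfa_weight)
            indexed = {}
            for mid, spec in build_standard_models().items():
                f = fit_wls(est, spec, weight=config.cfa_weight, seed=config.seed)
                indexed[mid] = fit_indices(f, baseline, est)
            comparison = compare_models(indexed, n=est.n)
            _write_csv(comparison.table, out / "cfa_fit.csv", index=False)
            pd.DataFrame(est.R, index=list(SYMPTOM_ITEMS), columns=list(SYMPTOM_ITEMS)).to_csv(
                out / "polychoric.csv"
            )
            manifest["cfa_selected"] = comparison.selected
            manifest["cfa_delta_bic"] = comparison.delta_bic
            manifest["outputs"] += ["cfa_fit.csv", "polychoric.csv"]
        stage("cfa", _cfa)

    if "network" in config.stages:
        def _network():
            net = EbicGlassoNetwork(
                gamma=config.network_gamma,
                correlation_input=config.network_correlation,
            ).fit(items)
            _write_csv(net.network_.edge_list(), out / "network_edges.csv", index=False)
            pd.DataFrame(net.weights_, index=net.network_.nodes,
                         columns=net.network_.nodes).to_csv(out / "network_adjacency.csv")
            _write_csv(net.centrality_, out / "centrality.csv")
            manifest["network_sparsity"] = net.sparsity_
            manifest["network_lambda"] = net.lambda_
            manifest["outputs"] += ["network_edges.csv", "network_adjacency.csv", "centrality.csv"]
        stage("network", _network)

    if "epi" in config.stages:
        def _epi():
            from itqnet.epi import exposure_summary_table

            _write_csv(exposure_summary_table(scored), out / "exposure_table.csv",
                       index=False)
            manifest["outputs"] += ["exposure_table.csv"]
            rows = []
            for cls_period in [c for c in scored.columns
                               if c.startswith(("intentional_", "unintentional_"))]:
                tab = pd.crosstab(scored["gender"], scored[cls_period])
                if tab.shape == (2, 2):
                    stat, df_, p = pearson_chi2(tab.to_numpy())
                    rows.append({"indicator": cls_period, "chi2": stat, "p": p})
            _write_csv(pd.DataFrame(rows), out / "gender_contrasts.csv", index=False)
            frames = []
            for adjusted in (False, True):
                reg = MultinomialDiagnosisRegression(adjusted=adjusted).fit(scored)
                ors = reg.odds_ratios_.assign(adjusted=adjusted)
                frames.append(ors)
            _write_csv(pd.concat(frames, ignore_index=True), out / "odds_ratios.csv", index=False)
            manifest["outputs"] += ["gender_contrasts.csv", "odds_ratios.csv"]
        stage("epi", _epi)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
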
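"""End-to-end orchestration of the subgroup network-comparison plan.

For each requested stratification scheme the pipeline builds the two
subgroups, z-scales each side, estimates both EBIC-glasso networks,
reports node/global strength and edge-weight similarity, runs the
permutation comparison of global strength, and (on request) the two
sensitivity analyses: excluding the CIS nodes from the disease-status
networks, and removing patients contributing an assessment to both sides.

Every stochastic stage derives its seed from the master seed and a fixed
stage tag via `stage_seed`, so adding a stage never perturbs the draws of
earlier stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as ch
from .ggm import EstimatorConfig, ebicglasso
from .instruments import CIS_NODES
from .metrics import edge_similarity, global_strength, strength_report
from .resampling import nct_global_strength
from .serialize import (
    network_to_csv,
    network_to_graphml,
    network_to_json,
    strength_to_csv,
)

log = logging.getLogger("promnet")

#: Fixed stage tags for seed derivation (documented, append-only).
STAGE_TAGS = {
    "simulate": 1,
    "nct": 2,
    "nct_cis_excluded": 3,
    "nct_dedup": 4,
    "selection": 5,
    "bootstrap": 6,
    "stability": 7,
}
SCHEME_TAGS = {"disease_status": 1, "tumor_grade": 2, "fatigue_status": 3}


def stage_seed(master: int, stage: str, scheme: str | None = None) -> int:
    """Deterministic per-stage seed below 2**31."""
    tags = [int(master), STAGE_TAGS[stage]]
    if scheme is not None:
        tags.append(SCHEME_TAGS[scheme])
    return int(np.random.SeedSequence(tags).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class PipelineConfig:
    schemes: tuple[str, ...] = ("disease_status", "tumor_grade", "fatigue_status")
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    selection_rule: str = "earliest"
    nct_B: int = 1000
    sensitivity: bool = True
    #: side kept by the cross-subgroup deduplication, per scheme
    dedup_keep: dict = field(default_factory=lambda: {
        "disease_status": "B", "tumor_grade": "B", "fatigue_status": "A",
    })
    seed: int = 0
    outdir: str | Path | None = None


def config_from_file(path, seed: int | None = None,
                     outdir=None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML or JSON mapping.

    Recognized keys: schemes, selection_rule, nct_B, sensitivity,
    dedup_keep, seed, and an `estimator` sub-mapping with EstimatorConfig
    fields (gamma, n_lambda, ...). `seed`/`outdir` arguments override the
    file.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    est = EstimatorConfig(**raw.pop("estimator", {}))
    if "schemes" in raw:
        raw["schemes"] = tuple(raw["schemes"])
    if seed is not None:
        raw["seed"] = seed
    if outdir is not None:
        raw["outdir"] = outdir
    return PipelineConfig(estimator=est, **raw)


def _estimate_side(side: pd.DataFrame, config: EstimatorConfig):
    scaled = ch.zscore_scale(side)
    return ebicglasso(ch.score_matrix(scaled), config)


def _nct_for(A: pd.DataFrame, B: pd.DataFrame, cfg: PipelineConfig,
             stage: str, scheme: str):
    return nct_global_strength(
        ch.score_matrix(ch.zscore_scale(A)),
        ch.score_matrix(ch.zscore_scale(B)),
        cfg.estimator, B=cfg.nct_B,
        seed=stage_seed(cfg.seed, stage, scheme),
    )


def run_scheme(table: pd.DataFrame, scheme: str, cfg: PipelineConfig) -> dict:
    """Run one stratification scheme; returns the summary dict."""
    spec = ch.SubgroupSpec(
        scheme=scheme,
        node_set="no_cis_17" if scheme == "fatigue_status" else "full_21",
        selection_rule=cfg.selection_rule,
        seed=stage_seed(cfg.seed, "selection", scheme),
    )
    A, B = ch.build_subgroups(table, spec)
    net_a = _estimate_side(A, cfg.estimator)
    net_b = _estimate_side(B, cfg.estimator)
    rep_a, rep_b = strength_report(net_a), strength_report(net_b)
    nct = _nct_for(A, B, cfg, "nct", scheme)

    summary = {
        "scheme": scheme,
        "n_A": int(len(A)),
        "n_B": int(len(B)),
        "n_nodes": net_a.n_nodes,
        "edge_count_A": net_a.edge_count(),
        "edge_count_B": net_b.edge_count(),
        "gs_A": rep_a.global_strength,
        "gs_B": rep_b.global_strength,
        "nct_p": nct.p_value,
        "edge_similarity": edge_similarity(net_a, net_b),
        "shared_patients": int(
            len(set(A["patient_id"]) & set(B["patient_id"]))),
    }

    if cfg.sensitivity:
        sens: dict = {}
        if scheme == "disease_status":
            A17 = ch.drop_nodes(A, list(CIS_NODES))
            B17 = ch.drop_nodes(B, list(CIS_NODES))
            nct17 = _nct_for(A17, B17, cfg, "nct_cis_excluded", scheme)
            sens["cis_excluded"] = {
                "n_nodes": 17,
                "gs_A": nct17.gs_A, "gs_B": nct17.gs_B, "nct_p": nct17.p_value,
            }
        Ad, Bd = ch.dedup_cross_subgroup(A, B, keep_side=cfg.dedup_keep[scheme])
        nctd = _nct_for(Ad, Bd, cfg, "nct_dedup", scheme)
        sens["dedup"] = {
            "keep_side": cfg.dedup_keep[scheme],
            "n_A": int(len(Ad)), "n_B": int(len(Bd)),
            "gs_A": nctd.gs_A, "gs_B": nctd.gs_B, "nct_p": nctd.p_value,
        }
        summary["sensitivity"] = sens

    summary["_networks"] = (net_a, net_b)
    summary["_strength"] = (rep_a, rep_b)
    return summary


def _write_scheme_outputs(outdir: Path, scheme: str, summary: dict) -> None:
    d = outdir / scheme
    (d / "networks").mkdir(parents=True, exist_ok=True)
    (d / "metrics").mkdir(exist_ok=True)
    net_a, net_b = summary.pop("_networks")
    rep_a, rep_b = summary.pop("_strength")
    for tag, net, rep in (("A", net_a, rep_a), ("B", net_b, rep_b)):
        network_to_csv(net, d / "networks" / f"network_{tag}.csv")
        network_to_json(net, d / "networks" / f"network_{tag}.json")
        network_to_graphml(net, d / "networks" / f"network_{tag}.graphml")
        strength_to_csv(rep, d / "metrics" / f"strength_{tag}.csv")
    with open(d / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(d / "report.txt", "w") as fh:
        fh.write(
            f"{scheme}: GS = {summary['gs_A']:.2f} vs. "
            f"GS = {summary['gs_B']:.2f}, p = {summary['nct_p']:.3g}\n"
            f"edge similarity rho = {summary['edge_similarity']:.2f}\n"
        )


def run_pipeline(table: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Run all requested schemes; optionally write a result bundle.

    A failing scheme is logged and skipped; the others continue.
    """
    report = ch.validate_table(table)
    if report["errors"]:
        raise ValueError("invalid input table: " + " | ".join(report["errors"]))
    for w in report["warnings"]:
        log.warning(w)

    results: dict = {"seed": cfg.seed, "schemes": {}}
    for scheme in cfg.schemes:
        try:
            results["schemes"][scheme] = run_scheme(table, scheme, cfg)
        except Exception as exc:  # keep other schemes running
            log.error("scheme %s failed: %s", scheme, exc)
            results["schemes"][scheme] = {"error": str(exc)}

    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for scheme, summary in results["schemes"].items():
            if "error" not in summary:
                _write_scheme_outputs(outdir, scheme, summary)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
    else:
        for summary in results["schemes"].values():
            summary.pop("_networks", None)
            summary.pop("_strength", None)
    return results
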
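"""End-to-end orchestration: inputs → repair status → neoantigens →
infiltration → phenotype/score → statistics report.

`run_all` executes the stages in dependency order from a
:class:`RunConfig` (real input files or a freshly simulated cohort),
writes one TSV per stage plus a summary and a machine-readable manifest
stamped with the configuration hash and seed, and returns everything
in memory.  With a fixed seed a rerun reproduces the outputs
bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import repair_status as rs
from .cohort_io import (
    ExpressionMatrix,
    compute_zscores,
    read_affinity,
    read_clinical,
    read_expression,
    read_gmt,
    read_maf,
    read_protein_fasta,
)
from .infiltration import call_infiltration, coinfiltration_matrix
from .neoantigen import call_neoantigens, neoantigen_burden, pairs_for_variant
from .phenotype_score import (
    activated_t_flag,
    assemble_phenotypes,
    panel_comparison,
    signature_table,
    subtype_association,
)
from .stats_core import km_logrank_hr, storey_q, t_test, two_proportion_z
from .synthetic_data import CYTOLYTIC_GENES, SimulationParams, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_all"]


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and offending input."""


@dataclass
class RunConfig:
    """Every analysis knob of a pipeline run in one place.

    Threshold defaults are the analysis' printed settings: SIFT < 0.05,
    CADD > 20, IC50 500 nM, infiltration q ≤ 0.10, combined-score cut
    ≤ 1.
    """

    # inputs (leave None and set simulate=True to generate a cohort)
    maf: str | None = None
    expression: str | None = None
    gmt: str | None = None
    clinical: str | None = None
    affinity: str | None = None
    proteins: str | None = None
    hla: str | None = None
    simulate: bool = False
    sim_params: dict = field(default_factory=dict)
    # thresholds
    sift_cut: float = 0.05
    cadd_cut: float = 20.0
    ic50_cut: float = 500.0
    q_cut: float = 0.10
    score_cut: int = 1
    # conventions
    tmb_mode: str = "all"
    burden_unit: str = "peptide"
    act_convention: str = "either"
    storey_lambda: float = 0.5
    permutation_B: int = 1000
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        value = float(obj)
        return None if np.isnan(value) else value
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _survival_entry(clinical, mask_high, time_col, event_col, label):
    frame = clinical.loc[mask_high.index]
    groups = np.where(mask_high, "high", "low")
    try:
        res = km_logrank_hr(frame[time_col], frame[event_col], groups)
    except ValueError as exc:
        return {"contrast": label, "error": str(exc)}
    # HR convention: second level vs first as ordered by appearance; report
    # high-vs-low explicitly
    first = pd.unique(pd.Series(groups))[0]
    hr = res.hr
    ci = res.hr_ci
    if hr is not None and first == "high":
        hr = 1.0 / hr
        ci = (1.0 / res.hr_ci[1], 1.0 / res.hr_ci[0])
    return {
        "contrast": label,
        "logrank_chi2": res.logrank_chi2,
        "logrank_p": res.logrank_p,
        "hr_high_vs_low": hr,
        "hr_ci": ci,
    }


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every stage and return the output bundle.

    Outputs: ``repair`` (per-sample status), ``tmb_split`` labels,
    ``neoantigen_burden``, ``infiltration`` calls, ``coinfiltration``,
    ``phenotype`` (groups + combined score), and ``summary`` with the
    headline statistical contrasts.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    outputs: dict[str, Any] = {}

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.simulate:
            params = SimulationParams(seed=config.seed, **config.sim_params)
            cohort = simulate_cohort(params)
            variants = cohort.variants
            matrix = cohort.expression
            sets = cohort.gene_sets
            clinical = cohort.clinical
            affinity = cohort.affinity
            proteins = cohort.proteins
            alleles = cohort.hla_alleles
            outputs["truth"] = cohort.truth
        else:
            if config.maf is None or config.expression is None or config.gmt is None:
                raise ValueError("maf, expression and gmt inputs are required (or set simulate: true)")
            variants = read_maf(config.maf)
            matrix = read_expression(config.expression)
            sets = read_gmt(config.gmt)
            clinical = read_clinical(config.clinical) if config.clinical else None
            affinity = read_affinity(config.affinity) if config.affinity else None
            proteins = read_protein_fasta(config.proteins) if config.proteins else {}
            alleles = (
                tuple(l.strip() for l in Path(config.hla).read_text().splitlines() if l.strip())
                if config.hla
                else ()
            )
    except Exception as exc:
        raise StageError(f"input stage failed: {exc}") from exc

    # ---- stage: repair status -----------------------------------------
    try:
        statuses = rs.classify_repair(
            variants,
            sift_cut=config.sift_cut,
            cadd_cut=config.cadd_cut,
            samples=matrix.samples,
            tmb_mode=config.tmb_mode,
        )
        repair = rs.status_frame(statuses)
        tmb_labels, tmb_median = rs.median_split(repair["tmb"].to_dict())
        repair["tmb_group"] = pd.Series(tmb_labels)
        outputs["repair"] = repair
        outputs["tmb_median"] = tmb_median
    except Exception as exc:
        raise StageError(f"repair-status stage failed: {exc}") from exc

    # ---- stage: neoantigen --------------------------------------------
    burdens = None
    if affinity is not None and proteins and alleles:
        try:
            by_sample = defaultdict(list)
            for v in variants:
                by_sample[v.sample_id].append(v)
            rows = []
            for sample in repair.index:
                pairs = []
                for v in by_sample.get(sample, ()):
                    pairs.extend(pairs_for_variant(v, proteins))
                expr = matrix.values[sample] if sample in matrix.values.columns else {}
                calls = call_neoantigens(
                    pairs, alleles, affinity, expr,
                    mut_cut=config.ic50_cut, wt_cut=config.ic50_cut,
                )
                rows.append(
                    {
                        "sample_id": sample,
                        "neoantigen_burden": neoantigen_burden(calls, unit=config.burden_unit),
                    }
                )
            burdens = pd.DataFrame(rows).set_index("sample_id")["neoantigen_burden"]
            outputs["neoantigen_burden"] = burdens
        except Exception as exc:
            raise StageError(f"neoantigen stage failed: {exc}") from exc

    # ---- stage: infiltration ------------------------------------------
    try:
        matrix = compute_zscores(matrix)
        calls = call_infiltration(
            matrix, sets, q_cut=config.q_cut, B=config.permutation_B, seed=config.seed
        )
        outputs["infiltration"] = calls
        try:
            r, p = coinfiltration_matrix(calls)
            outputs["coinfiltration"] = r
        except ValueError:
            outputs["coinfiltration"] = None
    except Exception as exc:
        raise StageError(f"infiltration stage failed: {exc}") from exc

    # ---- stage: phenotype ---------------------------------------------
    try:
        act = activated_t_flag(calls, convention=config.act_convention)
        phenotype = assemble_phenotypes(
            repair["any_variant"], act, matrix.zscores, score_cut=config.score_cut
        )
        outputs["phenotype"] = phenotype
    except Exception as exc:
        raise StageError(f"phenotype stage failed: {exc}") from exc

    # ---- stage: statistics report -------------------------------------
    try:
        summary: dict[str, Any] = {
            "n_samples": int(len(repair)),
            "tmb_median": float(outputs["tmb_median"]),
            "group_sizes": phenotype["group"].value_counts().to_dict(),
        }
        carrier = repair["any_variant"]
        if carrier.nunique() == 2:
            res = t_test(repair.loc[carrier, "tmb"], repair.loc[~carrier, "tmb"])
            summary["tmb_carrier_t"] = {"t": res.statistic, "p": res.p}
            if burdens is not None:
                res = t_test(burdens[carrier[burdens.index]], burdens[~carrier[burdens.index]])
                summary["neoantigen_carrier_t"] = {"t": res.statistic, "p": res.p}

        wide = calls.pivot(index="sample_id", columns="cell_type", values="infiltrated")
        high = repair["tmb_group"] == "high"
        for panel_name, split in (("tmb_high", high), ("score_low", phenotype["score_class"] == "low")):
            entry = {}
            ps = []
            for ct in ("Act_CD4", "Act_CD8"):
                if ct not in wide.columns:
                    continue
                flag = wide[ct].astype(bool)
                common = flag.index.intersection(split.index)
                s = split[common]
                f = flag[common]
                res = two_proportion_z(int(f[s].sum()), int(s.sum()), int(f[~s].sum()), int((~s).sum()))
                entry[ct] = {"z": res.statistic, "p": res.p}
                ps.append(res.p)
            if ps and not any(pd.isna(ps)):
                qs = storey_q(np.asarray(ps), lam=config.storey_lambda)
                for ct, q in zip([c for c in ("Act_CD4", "Act_CD8") if c in entry], qs):
                    entry[ct]["q"] = float(q)
            summary[f"infiltration_by_{panel_name}"] = entry

        panel = [g for g in rs.WNT_PANEL if g in matrix.values.index]
        if panel:
            comparison = panel_comparison(phenotype["group"], matrix, panel)
            outputs["panel_comparison"] = comparison
            ii_iv = comparison[comparison["comparison"].isin(["II vs IV", "IV vs II"])]
            summary["panel_II_vs_IV_p_adj"] = {
                row.gene: row.p_adj for row in ii_iv.itertuples(index=False)
            }
        signature_panel = [g for g in CYTOLYTIC_GENES if g in matrix.values.index]
        if signature_panel:
            volcano = signature_table(repair["tmb_group"], matrix, signature_panel)
            outputs["signature_table"] = volcano

        if clinical is not None:
            if "subtype" in clinical.columns and clinical["subtype"].notna().any():
                try:
                    assoc = subtype_association(repair["mmr_variant"], clinical["subtype"])
                    outputs["subtype_association"] = assoc
                    summary["mmr_subtype_min_q"] = float(assoc["q"].min())
                except ValueError as exc:
                    logger.warning("subtype association skipped: %s", exc)
            survival = []
            splits = {"tmb_high": high, "repair_variant": carrier}
            if burdens is not None:
                neo_labels, _ = rs.median_split(burdens.to_dict())
                splits["neoantigen_high"] = pd.Series(neo_labels) == "high"
            for label, mask in splits.items():
                mask = mask[mask.index.intersection(clinical.index)]
                if mask.nunique() < 2:
                    continue
                for time_col, event_col, tag in (
                    ("os_time", "os_event", "os"),
                    ("dfs_time", "dfs_event", "dfs"),
                ):
                    survival.append(_survival_entry(clinical, mask, time_col, event_col, f"{label}_{tag}"))
            summary["survival"] = survival
        outputs["summary"] = summary
    except Exception as exc:
        raise StageError(f"statistics stage failed: {exc}") from exc

    if config.outdir:
        _write_outputs(outputs, config)
    return outputs


def _write_outputs(outputs: Mapping[str, Any], config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []

    def emit(name: str, frame: pd.DataFrame, index: bool = True) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=index)
        files.append(name)

    emit("repair_status.tsv", outputs["repair"])
    if outputs.get("neoantigen_burden") is not None:
        emit("neoantigen_burden.tsv", outputs["neoantigen_burden"].to_frame())
    emit("infiltration.tsv", outputs["infiltration"], index=False)
    if outputs.get("coinfiltration") is not None:
        emit("coinfiltration.tsv", outputs["coinfiltration"])
    emit("phenotype.tsv", outputs["phenotype"])
    if outputs.get("panel_comparison") is not None:
        emit("panel_comparison.tsv", outputs["panel_comparison"], index=False)
    if outputs.get("signature_table") is not None:
        emit("signature_table.tsv", outputs["signature_table"], index=False)
    if outputs.get("subtype_association") is not None:
        emit("subtype_association.tsv", outputs["subtype_association"], index=False)

    summary_json = json.dumps(_jsonable(outputs["summary"]), indent=1, sort_keys=True)
    (outdir / "summary.json").write_text(summary_json)
    files.append("summary.json")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "files": files,
        "summary_sha256": hashlib.sha256(summary_json.encode()).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
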
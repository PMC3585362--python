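"""End-to-end analysis pipeline and report rendering.

``run_pipeline`` takes a pair CSV through ingest, ascertainment-classified
counts, the three concordance estimators, tetrachoric correlations,
ACE-family model comparison, prevalence and recurrence risks, and returns a
JSON-serializable report that also renders as a Markdown table in the style
of published twin-concordance tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import __version__
from .concordance import (
    ConcordanceKind,
    UndefinedEstimateError,
    casewise_concordance,
    pairwise_concordance,
    probandwise_concordance,
)
from .liability import (
    compare_models,
    contingency_from_records,
    fit_variance_model,
    tetrachoric_mle,
)
from .prevalence_risk import crude_prevalence, recurrence_risk_ratio
from .twin_data import (
    TwinPairRecord,
    Zygosity,
    acpa_positive_pair,
    aggregate_counts,
    read_pair_table,
)

logger = logging.getLogger("twinliab")


@dataclass
class PipelineConfig:
    """Options for :func:`run_pipeline`."""

    level: float = 0.95
    subsets: tuple[str, ...] = ("all", "acpa")
    models: tuple[str, ...] = ("ACE", "ADE", "AE", "CE", "E")
    fit_models: bool = True
    fit_tetrachoric: bool = True
    compute_component_ci: bool = False
    sex_layout: str = "common"
    seed: int = 0


def _concordance_block(counts, level: float) -> Optional[dict]:
    if counts.n_ascertained == 0:
        return None
    block = {"counts": {"C1": counts.C1, "C2": counts.C2, "D1": counts.D1,
                        "U": counts.U, "remainder": counts.remainder}}
    for name, fn in (
        ("casewise", casewise_concordance),
        ("probandwise", probandwise_concordance),
        ("pairwise", pairwise_concordance),
    ):
        try:
            est = fn(counts, level)
        except UndefinedEstimateError:
            block[name] = None
            continue
        pct, lo, hi = est.as_percent()
        block[name] = {
            "rate": est.rate, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "n_success": est.n_success, "n_trials": est.n_trials,
            "percent": pct, "percent_ci": [lo, hi],
        }
    return block


def run_pipeline(
    pair_csv: Union[str, Path, Sequence[TwinPairRecord]],
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Run the full twin analysis on a pair table.

    Accepts a CSV path or an already-loaded record list.  The report is a
    plain dict: concordance per zygosity and subset, tetrachoric
    correlations, variance-model comparison, prevalence and recurrence
    risks, plus provenance (input hash, config, package version).  For a
    fixed input and config the report is fully deterministic.
    """
    config = config or PipelineConfig()
    t_start = time.perf_counter()

    if isinstance(pair_csv, (str, Path)):
        raw = Path(pair_csv).read_bytes()
        input_hash = hashlib.sha256(raw).hexdigest()
        records = read_pair_table(pair_csv)
        source = str(pair_csv)
    else:
        records = list(pair_csv)
        input_hash = hashlib.sha256(
            "\n".join(r.pair_id for r in records).encode()
        ).hexdigest()
        source = "<records>"
    logger.info("ingest: %d pairs from %s", len(records), source)

    report: dict = {
        "provenance": {
            "source": source,
            "input_sha256": input_hash,
            "n_pairs": len(records),
            "version": __version__,
            "config": {
                "level": config.level,
                "subsets": list(config.subsets),
                "models": list(config.models),
                "sex_layout": config.sex_layout,
                "seed": config.seed,
            },
        },
        "concordance": {},
        "tetrachoric": {},
        "models": None,
        "prevalence": None,
        "recurrence_risk": {},
        "status": "ok",
    }

    subset_rules = {"all": None, "acpa": acpa_positive_pair}
    any_estimable = False
    for subset in config.subsets:
        rule = subset_rules[subset]
        report["concordance"][subset] = {}
        for zyg in Zygosity:
            counts = aggregate_counts(records, zygosity=zyg, subset=rule)
            block = _concordance_block(counts, config.level)
            report["concordance"][subset][zyg.value] = block
            any_estimable = any_estimable or block is not None
    if not any_estimable:
        report["status"] = "no estimable groups"

    # prevalence among all responding individuals
    n_individuals = 2 * len(records)
    n_cases = sum(r.n_affected for r in records)
    if n_individuals > 0:
        prev = crude_prevalence(n_cases, n_individuals, config.level)
        report["prevalence"] = {
            "cases": prev.cases, "denominator": prev.denominator,
            "crude": prev.crude, "ci_low": prev.ci_low, "ci_high": prev.ci_high,
        }
        if prev.crude > 0:
            for zyg in Zygosity:
                block = report["concordance"]["all"].get(zyg.value)
                if not block:
                    continue
                risks = {}
                for kind in ("probandwise", "casewise"):
                    est_d = block.get(kind)
                    if est_d is None:
                        continue
                    risks[kind] = est_d["rate"] / prev.crude
                report["recurrence_risk"][zyg.value] = risks

    if config.fit_tetrachoric:
        for zyg in Zygosity:
            tables = contingency_from_records(records, zyg)
            table = tables[0] if tables else None
            if table is None or table.n_neither == 0 or (table.n_both + table.n_one) == 0:
                report["tetrachoric"][zyg.value] = None
                continue
            est = tetrachoric_mle(table, level=config.level)
            report["tetrachoric"][zyg.value] = {
                "rho": est.rho, "threshold": est.threshold,
                "ci_low": est.ci_low, "ci_high": est.ci_high, "loglik": est.loglik,
            }
        logger.info("tetrachoric: done (%.1fs)", time.perf_counter() - t_start)

    if config.fit_models:
        tables = []
        for zyg in Zygosity:
            by_sex = config.sex_layout == "per-sex"
            for tbl in contingency_from_records(records, zyg, by_sex=by_sex):
                if tbl.n_total > 0:
                    tables.append(tbl)
        have_mz = any(t.zygosity is Zygosity.MZ for t in tables)
        have_dz = any(t.zygosity is not Zygosity.MZ for t in tables)
        if have_mz and have_dz:
            fits = [
                fit_variance_model(
                    tables, structure=m, sex_layout=config.sex_layout,
                    level=config.level, compute_ci=config.compute_component_ci,
                )
                for m in config.models
            ]
            comparison = compare_models(fits)
            report["models"] = {
                "fits": [
                    {
                        "structure": f.structure,
                        "a2": f.a2, "c2": f.c2, "d2": f.d2, "e2": f.e2,
                        "rho_mz": f.rho_mz, "rho_dz": f.rho_dz,
                        "thresholds": f.thresholds,
                        "loglik": f.loglik, "aic": f.aic,
                        "n_free_params": f.n_free_params,
                        "component_ci": {k: list(v) for k, v in f.component_ci.items()},
                    }
                    for f in fits
                ],
                "delta_aic": dict(comparison.delta_aic),
                "lrt": {f"{a}->{b}": v for (a, b), v in comparison.lrt.items()},
                "selected": comparison.selected,
            }
            logger.info("models: done (%.1fs)", time.perf_counter() - t_start)

    return report


def render_markdown(report: dict) -> str:
    """Render the concordance block as a published-style Markdown table."""
    lines = [
        "| Subset | Zygosity | C1 | C2 | D1 | Casewise % (95% CI) | Probandwise % (95% CI) | Pairwise % (95% CI) |",
        "|---|---|---|---|---|---|---|---|",
    ]

    def cell(block, kind):
        d = block.get(kind)
        if d is None:
            return "-"
        return f"{d['percent']:.1f} ({d['percent_ci'][0]:.1f} to {d['percent_ci'][1]:.1f})"

    for subset, groups in report.get("concordance", {}).items():
        for zyg, block in groups.items():
            if block is None:
                lines.append(f"| {subset} | {zyg} | - | - | - | - | - | - |")
                continue
            c = block["counts"]
            lines.append(
                f"| {subset} | {zyg} | {c['C1']} | {c['C2']} | {c['D1']} | "
                f"{cell(block, 'casewise')} | {cell(block, 'probandwise')} | {cell(block, 'pairwise')} |"
            )
    tet = report.get("tetrachoric") or {}
    if any(v for v in tet.values()):
        lines.append("")
        lines.append("| Zygosity | Tetrachoric r (95% CI) |")
        lines.append("|---|---|")
        for zyg, d in tet.items():
            if d:
                lines.append(f"| {zyg} | {d['rho']:.2f} ({d['ci_low']:.2f} to {d['ci_high']:.2f}) |")
    return "\n".join(lines)


def write_report(report: dict, json_path: Union[str, Path], md_path: Optional[Union[str, Path]] = None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=2, sort_keys=True))
    if md_path is not None:
        Path(md_path).write_text(render_markdown(report) + "\n")
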
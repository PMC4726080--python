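"""End-to-end orchestration: one config in, all report tables and a JSON
summary out.

Stages run in the order of the underlying analysis: catalog -> augmented
network -> module detection -> connectivity/co-expression -> tissue
classification -> disease network. Stages whose inputs are not configured
are skipped with explicit markers; any stage failure aborts with a
stage-labeled error, keeping partial outputs. Each permutation stage draws
from its own substream derived from (seed, stage name), so adding a stage
never perturbs another stage's random numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import yaml

from . import io as cio
from .assembly import assemble_augmented_network
from .disease import (
    build_incidence,
    disease_enrichment_table,
    disease_nestedness_index,
    disease_report,
)
from .mcode import McodeParams, mcode_find_modules, module_cofactor_enrichment, module_report
from .tissues import classify_all, compare_expressed_in_all, enriched_share_table
from .topology import coexpression_by_cofactor, CoexpressionResult, hub_permutation_test
from .types import SOURCE_GWAS, SOURCE_OMIM, ValidationError

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    catalog: str
    ppi: Optional[str] = None
    expression: Optional[str] = None
    diseases_gwas: Optional[str] = None
    diseases_omim: Optional[str] = None
    universe: Optional[str] = None
    outdir: str = "cofactornet_out"
    seed: int = 0
    n_perm: int = 10000
    hub_fraction: float = 0.02
    detection_threshold: float = 1.0
    fold: float = 5.0
    min_disease_genes: int = 5
    mcode: McodeParams = field(default_factory=McodeParams)

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if not 0.0 < self.hub_fraction < 1.0:
            raise ValidationError("hub_fraction must be in (0, 1)")
        self.mcode.validate()

    def to_dict(self) -> Dict[str, object]:
        d = asdict(self)
        return d


_CONFIG_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}
_MCODE_KEYS = {f.name for f in dataclasses.fields(McodeParams)}


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON config; unknown keys are errors, missing
    optional keys get documented defaults, and the effective configuration is
    logged."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} must contain a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    mcode_raw = raw.pop("mcode", {}) or {}
    if not isinstance(mcode_raw, dict):
        raise ValidationError("mcode section must be a mapping")
    unknown = set(mcode_raw) - _MCODE_KEYS
    if unknown:
        raise ValidationError(f"unknown mcode keys: {sorted(unknown)}")
    if "catalog" not in raw:
        raise ValidationError("config requires a catalog path")
    try:
        config = PipelineConfig(mcode=McodeParams(**mcode_raw), **raw)
    except TypeError as exc:
        raise ValidationError(f"bad config value: {exc}") from None
    config.validate()
    logger.info("effective config: %s", json.dumps(config.to_dict(), sort_keys=True))
    return config


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage substream seed below 2^31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def run_all(config: PipelineConfig) -> Dict[str, object]:
    """Run every configured stage; writes the stage outputs plus
    ``summary.json`` under ``config.outdir`` and returns the summary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, object] = {"seed": config.seed}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage label
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    # -- catalog ------------------------------------------------------------
    catalog = _stage("catalog")(lambda: cio.read_cofactor_table(config.catalog))
    summary["catalog"] = catalog.summary()

    # -- network assembly + modules ----------------------------------------
    if config.ppi:
        def assemble():
            ppi = cio.read_ppi(config.ppi)
            net, report = assemble_augmented_network(catalog, ppi)
            cio.write_network(net, outdir / "net.graphml")
            with open(outdir / "assembly_report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
            return ppi, net, report

        ppi, net, report = _stage("assembly")(assemble)
        summary["assembly"] = report.to_dict()

        def modules_stage():
            modules = mcode_find_modules(net, config.mcode)
            universe = set(net.graph.nodes)
            enr = module_cofactor_enrichment(modules, catalog, universe)
            table = module_report(modules, catalog, enr)
            table.to_csv(outdir / "modules.tsv", sep="\t", index=False)
            return modules, table

        modules, module_table = _stage("modules")(modules_stage)
        summary["modules"] = {
            "n_detected": len(modules.all_modules),
            "n_reported": len(modules.modules),
            "sizes": [len(m) for m in modules.modules],
        }

        def hub_stage():
            return hub_permutation_test(
                ppi,
                set(catalog.proteins) & set(ppi.nodes),
                threshold=config.hub_fraction,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, "hubs"),
            )

        hubs = _stage("hubs")(hub_stage)
        summary["hubs"] = {
            "threshold": hubs.hub_fraction_threshold,
            "n_hubs": len(hubs.hubs),
            "observed_cofactor_hub_count": hubs.observed_cofactor_hub_count,
            "observed_fraction": hubs.test.observed,
            "p_value": hubs.test.p_value,
        }
    else:
        summary["assembly"] = "skipped"
        summary["modules"] = "skipped"
        summary["hubs"] = "skipped"

    # -- co-expression + tissue classification ------------------------------
    if config.expression:
        expr = _stage("expression")(lambda: cio.read_expression(config.expression))

        def coexpr_stage():
            results = coexpression_by_cofactor(
                expr, catalog, n_perm=config.n_perm, seed=stage_seed(config.seed, "coexpr")
            )
            present = set(catalog.proteins) & set(expr.genes)
            s = catalog.summary()
            per_cofactor = []
            # coverage carries both possible denominators explicitly
            payload = {
                "coverage": {
                    "n_catalog_proteins_in_expression": len(present),
                    "pct_of_catalog_proteins": 100.0 * len(present) / s["n_proteins"],
                    "pct_of_unique_interactions": 100.0 * len(present) / s["n_unique_pairs"],
                },
                "cofactors": per_cofactor,
            }
            for r in results:
                if isinstance(r, CoexpressionResult):
                    per_cofactor.append(
                        {
                            "cofactor_id": r.cofactor_id,
                            "group_size": r.group_size,
                            "mean_pairwise_r": r.mean_pairwise_r,
                            "p_value": r.test.p_value,
                        }
                    )
                else:
                    per_cofactor.append(
                        {
                            "cofactor_id": r.cofactor_id,
                            "group_size": r.group_size,
                            "excluded": r.reason,
                        }
                    )
            with open(outdir / "topo.json", "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
            return payload

        summary["coexpression"] = _stage("coexpression")(coexpr_stage)

        def tissue_stage():
            classification, counts = classify_all(
                expr, catalog, config.detection_threshold, config.fold
            )
            counts.to_csv(outdir / "tissue_categories.tsv", sep="\t", index=False)
            share = enriched_share_table(classification, catalog)
            share.to_csv(outdir / "tissues.tsv", sep="\t", index=False)
            test = compare_expressed_in_all(
                classification,
                catalog,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, "tissues"),
            )
            return {
                "category_counts": {
                    row["category"]: int(row["n_genes"]) for _, row in counts.iterrows()
                },
                "expressed_in_all_observed_fraction": test.observed,
                "expressed_in_all_p_value": test.p_value,
            }

        summary["tissues"] = _stage("tissues")(tissue_stage)
    else:
        summary["coexpression"] = "skipped"
        summary["tissues"] = "skipped"

    # -- disease networks ----------------------------------------------------
    disease_summaries: Dict[str, object] = {}
    for source, path in ((SOURCE_GWAS, config.diseases_gwas), (SOURCE_OMIM, config.diseases_omim)):
        if not path:
            disease_summaries[source] = "skipped"
            continue

        def disease_stage(source=source, path=path):
            dmap = cio.read_disease_map(path, source)
            incidence = build_incidence(catalog, dmap)
            nest = disease_nestedness_index(incidence, min_genes=config.min_disease_genes)
            table = disease_report(incidence, nest, dmap, len(catalog.cofactors))
            table.to_csv(outdir / f"disease_{source}.tsv", sep="\t", index=False)
            out = {
                "n_diseases": len(dmap),
                "n_linked": len(incidence.diseases),
                "pct_linked": (
                    float(100.0 * len(incidence.diseases) / len(dmap)) if len(dmap) else 0.0
                ),
                "n_retained": len(nest.row_order),
                "matrix_nodf": nest.matrix_nodf,
                "ranking": nest.row_order,
            }
            if config.universe:
                universe = set(cio.read_gene_list(config.universe))
                universe |= set(catalog.proteins)
                for gs in dmap.entries.values():
                    universe |= gs
                enr = disease_enrichment_table(catalog, dmap, universe)
                enr.to_csv(outdir / f"disease_{source}_enrichment.tsv", sep="\t", index=False)
                out["n_enriched_q05"] = int((enr["q_value"] <= 0.05).sum()) if len(enr) else 0
            return out

        disease_summaries[source] = _stage(f"disease_{source}")(disease_stage)
    summary["diseases"] = disease_summaries

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
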
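"""End-to-end orchestration: normalize -> atlas -> DE -> cross-species -> enrichment.

A single YAML config names the inputs, thresholds and contrasts; the
runner executes the stages in order, writes one TSV per result plus a
machine-readable ``manifest.json``, and fails fast with a stage-named
error. Outputs are sorted deterministically and the manifest carries no
timestamps, so identical config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import counts as counts_mod
from . import diffexpr, enrichment, orthology

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "expression_threshold": 4.0,
    "cv_max": 0.15,
    "tau_max": None,
    "lfc_min": 1.0,
    "padj_max": 0.05,
    "alpha": 0.05,
}

STAGES = ("normalize", "atlas", "de", "crossspecies", "enrichment")


class PipelineError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``contrasts`` entries: {name, column, group_a: [...], group_b: [...]}.
    ``deg_specs`` entries map DEG sets into organ/direction strata, either
    from a computed contrast ({species, organ, direction, contrast}) or
    from a file ({species, organ, direction, path}).
    ``pif`` block: {labels: path, ortholog_maps: {species: path},
    samples: [{name, species, contrast | path}], sided: greater}.
    """

    counts: str
    metadata: str
    out_dir: str
    contrasts: list[dict] = field(default_factory=list)
    orthogroups: str | None = None
    deg_specs: list[dict] = field(default_factory=list)
    pif: dict | None = None
    thresholds: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for path in self.input_paths():
            if not os.path.exists(path):
                raise FileNotFoundError(f"configured input does not exist: {path}")
        if not (0 < self.thresholds["padj_max"] <= 1):
            raise ValueError("padj_max must be in (0, 1]")
        if self.thresholds["expression_threshold"] <= 0:
            raise ValueError("expression_threshold must be positive")
        if self.thresholds["cv_max"] <= 0:
            raise ValueError("cv_max must be positive")

    def input_paths(self) -> list[str]:
        paths = [self.counts, self.metadata]
        if self.orthogroups:
            paths.append(self.orthogroups)
        for spec in self.deg_specs:
            if "path" in spec:
                paths.append(spec["path"])
        if self.pif:
            paths.append(self.pif["labels"])
            paths.extend(self.pif.get("ortholog_maps", {}).values())
            for sample in self.pif.get("samples", []):
                if "path" in sample:
                    paths.append(sample["path"])
        return paths

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))

        def absolute(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        for key in ("counts", "metadata", "orthogroups"):
            if raw.get(key):
                raw[key] = absolute(raw[key])
        for spec in raw.get("deg_specs", []):
            if "path" in spec:
                spec["path"] = absolute(spec["path"])
        if raw.get("pif"):
            raw["pif"]["labels"] = absolute(raw["pif"]["labels"])
            raw["pif"]["ortholog_maps"] = {
                sp: absolute(p) for sp, p in raw["pif"].get("ortholog_maps", {}).items()
            }
            for sample in raw["pif"].get("samples", []):
                if "path" in sample:
                    sample["path"] = absolute(sample["path"])
        if raw.get("out_dir"):
            raw["out_dir"] = absolute(raw["out_dir"])
        return cls(**raw)


def _write(df: pd.DataFrame, out_dir: str, name: str, manifest: dict,
           index_label: str | None = None) -> str:
    path = os.path.join(out_dir, name)
    df.to_csv(path, sep="\t", index=index_label is not None,
              index_label=index_label, float_format="%.10g")
    manifest["outputs"].append(name)
    return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages; returns the manifest dictionary."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest: dict[str, Any] = {
        "stages": [],
        "thresholds": {k: v for k, v in cfg.thresholds.items()},
        "seed": cfg.seed,
        "inputs": sorted(os.path.basename(p) for p in cfg.input_paths()),
        "outputs": [],
        "counts": {},
    }

    # --- normalize -------------------------------------------------------
    stage = "normalize"
    try:
        cm = counts_mod.load_count_matrix(cfg.counts, cfg.metadata)
        n_before = cm.counts.shape[0]
        cm, dropped = counts_mod.drop_allzero_genes(cm)
        sf = counts_mod.estimate_size_factors(cm)
        norm = counts_mod.normalize_counts(cm, sf)
        norm = norm.sort_index()
        _write(sf.to_frame().sort_index(), cfg.out_dir, "size_factors.tsv",
               manifest, index_label="sample_id")
        _write(norm, cfg.out_dir, "normalized.tsv", manifest, index_label="gene_id")
        manifest["counts"][stage] = {
            "genes_in": n_before, "genes_dropped_allzero": len(dropped),
            "genes_out": int(norm.shape[0]), "samples": int(norm.shape[1]),
        }
        manifest["stages"].append(stage)
        logger.info("normalize: %d genes, %d samples (%d all-zero dropped)",
                    norm.shape[0], norm.shape[1], len(dropped))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage name
        raise PipelineError(stage, str(exc)) from exc

    # --- atlas -----------------------------------------------------------
    stage = "atlas"
    try:
        meta = cm.metadata
        atlas_samples = meta.index[meta["group"] == "atlas"]
        if len(atlas_samples) == 0:
            atlas_samples = meta.index
        norm_atlas = norm[list(atlas_samples)]
        tm, n_rep = counts_mod.tissue_means(norm_atlas, meta)
        calls = atlas_mod.call_expressed(tm, cfg.thresholds["expression_threshold"])
        breadth, hist = atlas_mod.expression_breadth(calls)
        stats_df = atlas_mod.gene_variability_stats(
            norm_atlas, tm, cfg.thresholds["expression_threshold"])
        constitutive = atlas_mod.find_constitutive_genes(
            stats_df, cfg.thresholds["cv_max"], cfg.thresholds["tau_max"])
        sim = atlas_mod.sample_similarity(norm_atlas)
        _write(tm.sort_index(), cfg.out_dir, "tissue_means.tsv", manifest,
               index_label="gene_id")
        _write(calls.sort_index().astype(int), cfg.out_dir, "expressed_calls.tsv",
               manifest, index_label="gene_id")
        _write(hist.to_frame(), cfg.out_dir, "breadth_histogram.tsv", manifest,
               index_label="breadth")
        _write(stats_df.sort_index(), cfg.out_dir, "gene_stats.tsv", manifest,
               index_label="gene_id")
        _write(constitutive, cfg.out_dir, "constitutive_genes.tsv", manifest,
               index_label="gene_id")
        _write(sim, cfg.out_dir, "sample_similarity.tsv", manifest,
               index_label="sample_id")
        manifest["counts"][stage] = {
            "tissues": int(tm.shape[1]),
            "expressed_any_tissue": int((breadth > 0).sum()),
            "expressed_all_tissues": int((breadth == tm.shape[1]).sum()),
            "constitutive": int(constitutive.shape[0]),
        }
        manifest["stages"].append(stage)
        logger.info("atlas: %d/%d genes expressed in >=1 tissue; %d constitutive",
                    (breadth > 0).sum(), len(breadth), constitutive.shape[0])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- differential expression ----------------------------------------
    stage = "de"
    de_results: dict[str, pd.DataFrame] = {}
    try:
        manifest["counts"][stage] = {}
        for spec in cfg.contrasts:
            contrast = diffexpr.contrast_from_metadata(
                cm.metadata, spec["column"], spec["group_a"], spec["group_b"],
                name=spec["name"])
            res = diffexpr.run_de_contrast(
                cm, contrast, lfc_min=cfg.thresholds["lfc_min"],
                padj_max=cfg.thresholds["padj_max"])
            res = res.sort_index()
            de_results[spec["name"]] = res
            _write(res, cfg.out_dir, f"de_{spec['name']}.tsv", manifest,
                   index_label="gene_id")
            n_up = int((res["status"] == "up").sum())
            n_down = int((res["status"] == "down").sum())
            manifest["counts"][stage][spec["name"]] = {
                "tested": int(res["tested"].sum()), "up": n_up, "down": n_down,
            }
            logger.info("de %s: %d up, %d down of %d tested",
                        spec["name"], n_up, n_down, int(res["tested"].sum()))
        if cfg.contrasts:
            manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- cross-species orthogroup intersection --------------------------
    stage = "crossspecies"
    try:
        if cfg.orthogroups and cfg.deg_specs:
            table = orthology.parse_orthogroups(cfg.orthogroups)
            strata: dict[tuple[str, str], None] = {}
            degs = orthology.StratifiedDEGSets({})
            for spec in cfg.deg_specs:
                organ, direction = spec["organ"], spec["direction"]
                if "path" in spec:
                    genes = enrichment.read_gene_list(spec["path"])
                else:
                    res = de_results[spec["contrast"]]
                    genes = diffexpr.deg_sets(res)[direction]
                degs.add(spec["species"], organ, direction, genes)
                strata[(organ, direction)] = None
            manifest["counts"][stage] = {}
            for organ, direction in strata:
                report = orthology.shared_orthogroups(table, degs, organ, direction)
                frame = orthology.report_to_frame(report)
                _write(frame, cfg.out_dir, f"venn_{organ}_{direction}.tsv", manifest)
                manifest["counts"][stage][f"{organ}_{direction}"] = {
                    "tagged_orthogroups": int(frame.shape[0]),
                    "triple_intersection": len(report.triple_intersection),
                }
            manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- enrichment (label scan over DEG samples) ------------------------
    stage = "enrichment"
    try:
        if cfg.pif:
            labels = enrichment.read_gene_list(cfg.pif["labels"])
            maps = {sp: orthology.read_ortholog_map(p)
                    for sp, p in cfg.pif["ortholog_maps"].items()}
            samples = []
            for sample in cfg.pif.get("samples", []):
                if "path" in sample:
                    deg = enrichment.read_gene_list(sample["path"])
                else:
                    sets = diffexpr.deg_sets(de_results[sample["contrast"]])
                    deg = sorted(sets["up"] | sets["down"])
                samples.append((sample["name"], sample["species"], deg))
            report = enrichment.pif_scan(
                samples, maps, labels, alpha=cfg.thresholds["alpha"],
                sided=cfg.pif.get("sided", "greater"))
            _write(report, cfg.out_dir, "pif_scan.tsv", manifest)
            manifest["counts"][stage] = {
                "samples": int(report.shape[0]),
                "significant": int(report["significant"].sum()),
            }
            manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    manifest["outputs"] = sorted(manifest["outputs"])
    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
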
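"""End-to-end orchestration: one config in, all stage outputs plus a
machine-readable ``summary.json`` out.

Stages: (simulate | load) → DEG calling per contrast → FPKM strata →
cis/trans ratio distributions and peak calls → compensated genes →
cross-contrast overlaps → strain clustering → optional functional-group
distributions and over-representation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import clustering, differential, dosage, io, setops
from .simulate import SimulationConfig, StrainSpec, simulate, write_truth

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("dosagescope")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, resolvable from a single YAML file."""

    contrasts: list[dict[str, str]]
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    reference_extra: dict[str, list[str]] = field(default_factory=dict)
    fold_threshold: float = 1.5
    p_threshold: float = 0.05
    fdr: float = 0.05
    bin_width: float = 0.05
    cap: float = 3.0
    strata_boundaries: tuple[float, float] = (10.0, 100.0)
    gene_sets: str | None = None
    de_method: str = "welch_log"
    plots: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        thresholds = raw.pop("thresholds", {}) or {}
        return cls(
            contrasts=[dict(c) for c in raw.get("contrasts", [])],
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            reference_extra={
                str(k): [str(c) for c in v]
                for k, v in (raw.get("reference_extra") or {}).items()
            },
            fold_threshold=float(thresholds.get("fold", 1.5)),
            p_threshold=float(thresholds.get("p", 0.05)),
            fdr=float(thresholds.get("fdr", 0.05)),
            bin_width=float(raw.get("bin_width", 0.05)),
            cap=float(raw.get("cap", 3.0)),
            strata_boundaries=tuple(raw.get("strata_boundaries", (10.0, 100.0))),
            gene_sets=raw.get("gene_sets"),
            de_method=raw.get("de_method", "welch_log"),
            plots=bool(raw.get("plots", False)),
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _simulation_config(raw: dict, seed: int) -> SimulationConfig:
    raw = dict(raw or {})
    strains = raw.pop("strains", None)
    raw.setdefault("seed", seed)
    if strains is not None:
        raw["strains"] = [
            StrainSpec(
                strain_id=s["strain_id"],
                extra_chromosomes=tuple(str(c) for c in s.get("extra_chromosomes", ())),
                **{
                    k: s[k]
                    for k in ("cis_mixture", "trans_mixture")
                    if k in s
                },
            )
            for s in strains
        ]
    return SimulationConfig(**raw)


def _load_or_simulate(config: PipelineConfig, out_dir: Path):
    if (config.simulate is None) == (config.inputs is None):
        raise ValueError("config must provide exactly one of 'simulate' or 'inputs'")
    if config.simulate is not None:
        sim = simulate(_simulation_config(config.simulate, config.seed))
        data_dir = out_dir / "simulated"
        data_dir.mkdir(parents=True, exist_ok=True)
        io.write_expression(sim.matrix, data_dir / "expression.tsv")
        io.write_sample_sheet(sim.sample_sheet, data_dir / "samples.tsv")
        io.write_annotation(sim.annotation, data_dir / "annotation.tsv")
        io.write_karyotypes(sim.karyotypes, data_dir / "karyotype.yaml")
        write_truth(sim.truth, data_dir / "truth.tsv")
        return sim.matrix, sim.sample_sheet, sim.annotation, sim.karyotypes
    paths = config.inputs
    sheet = io.read_sample_sheet(paths["sample_sheet"])
    matrix = io.read_expression(paths["expression"], sheet)
    annotation = io.read_annotation(paths["annotation"], paths.get("annotation_format"))
    karyotypes = io.read_karyotypes(paths["karyotype"], universe=annotation)
    return matrix, sheet, annotation, karyotypes


def _validate_strains(config, sheet, karyotypes):
    for contrast in config.contrasts:
        for role in ("case", "ctrl"):
            strain = contrast[role]
            if strain not in sheet:
                raise ValueError(f"contrast strain {strain!r} not in sample sheet")
            if strain not in karyotypes:
                raise ValueError(f"contrast strain {strain!r} not in karyotype config")


def run_pipeline(config: PipelineConfig | dict, out_dir: str | Path) -> dict:
    """Run every stage, write per-stage artifacts under ``out_dir`` and
    return (and write) the aggregated ``summary.json`` dict.  Deterministic
    for a fixed config seed."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    if not config.contrasts:
        raise ValueError("config lists no contrasts")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    matrix, sheet, annotation, karyotypes = _load_or_simulate(config, out_dir)
    _validate_strains(config, sheet, karyotypes)
    gene_sets = io.read_gene_sets(config.gene_sets) if config.gene_sets else None

    unannotated = [g for g in matrix.gene_ids if g not in annotation]
    if unannotated:
        log.info(
            "%d matrix genes lack a chromosome assignment; retained for DE, "
            "excluded from cis/trans partitioning", len(unannotated),
        )
    log.info(
        "thresholds: fold=%.2f p=%.3f fdr=%.3f bin=%.2f cap=%.1f strata=%s",
        config.fold_threshold, config.p_threshold, config.fdr,
        config.bin_width, config.cap, list(config.strata_boundaries),
    )

    means = differential.mean_expression(matrix, sheet)
    summary: dict[str, Any] = {
        "seed": config.seed,
        "n_genes": len(matrix.gene_ids),
        "strains": sheet.strains,
        "thresholds": {
            "fold": config.fold_threshold,
            "p": config.p_threshold,
            "fdr": config.fdr,
        },
        "contrasts": {},
    }
    deg_tables: dict[str, pd.DataFrame] = {}
    up_sets: dict[str, frozenset] = {}
    down_sets: dict[str, frozenset] = {}
    ratio_rows = []
    peaks_json: dict[str, dict] = {}

    for contrast in config.contrasts:
        case, ctrl = contrast["case"], contrast["ctrl"]
        name = f"{case}_vs_{ctrl}"
        stage = f"contrast {name}"
        try:
            deg = differential.call_degs(
                matrix, sheet, case, ctrl,
                fold_threshold=config.fold_threshold,
                p_threshold=config.p_threshold,
                method=config.de_method,
            )
            strata = differential.stratify(means[ctrl], config.strata_boundaries)
            deg_out = deg.copy()
            deg_out["stratum"] = strata.reindex(deg.index)
            deg_out.to_csv(out_dir / f"degs_{name}.tsv", sep="\t", index_label="gene_id")
            strat_summary = differential.stratum_summary(deg, strata)

            extra = config.reference_extra.get(case)
            partition = dosage.partition_cis_trans(
                annotation, karyotypes[case],
                reference_extra=set(extra) if extra else None,
            )
            peaks: dict[str, dict | None] = {}
            for subset_name, genes in (("cis", partition.cis_genes), ("trans", partition.trans_genes)):
                dist = dosage.ratio_distribution(
                    means[case], means[ctrl], genes,
                    bin_width=config.bin_width, cap=config.cap,
                    subset_label=f"{name}:{subset_name}", allow_empty=True,
                )
                ratio_rows.append(dist.to_frame())
                if dist.is_empty:
                    peaks[subset_name] = None
                    continue
                call = dosage.peak_call(dist)
                peaks[subset_name] = {
                    "modal_midpoint": call.modal_midpoint,
                    "classification": call.classification,
                    "tolerance": call.tolerance,
                    "median_ratio": dist.median(),
                    "n_genes": dist.n_genes,
                }
                if config.plots:
                    from .plotting import plot_ratio_distribution

                    plot_ratio_distribution(dist, out_dir / f"ratios_{name}_{subset_name}.png")
            peaks_json[name] = peaks

            comp = setops.compensated_genes(deg, partition, config.p_threshold)
            pd.Series(sorted(comp), name="gene_id").to_csv(
                out_dir / f"compensated_{name}.tsv", sep="\t", index=False
            )

            deg_tables[name] = deg
            up_sets[name] = frozenset(deg.index[deg["status"] == "up"])
            down_sets[name] = frozenset(deg.index[deg["status"] == "down"])
            summary["contrasts"][name] = {
                "n_up": len(up_sets[name]),
                "n_down": len(down_sets[name]),
                "n_unexpressed": int((deg["status"] == "unexpressed").sum()),
                "n_compensated_cis": len(comp),
                "strata": json.loads(strat_summary.to_json(orient="index")),
                "peaks": peaks,
            }

            if gene_sets is not None:
                groups = dosage.group_distributions(
                    means[case], means[ctrl], gene_sets,
                    bin_width=config.bin_width, cap=config.cap,
                )
                group_summary = {}
                for gname, gdist in groups.items():
                    ratio_rows.append(gdist.to_frame())
                    group_summary[gname] = (
                        None if gdist.is_empty
                        else {"n_genes": gdist.n_genes, **dosage.extreme_fraction(gdist)}
                    )
                summary["contrasts"][name]["functional_groups"] = group_summary
                universe = deg.index[deg["status"] != "unexpressed"]
                for direction, genes in (("up", up_sets[name]), ("down", down_sets[name])):
                    if genes:
                        table = setops.enrich(genes, universe, gene_sets, fdr=config.fdr)
                        table.to_csv(
                            out_dir / f"enrichment_{name}_{direction}.tsv",
                            sep="\t", index=False,
                        )
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed: {stage}: {exc}") from exc

    if len(up_sets) >= 2:
        take = list(up_sets)[:4]
        summary["overlaps"] = {
            "up": setops.overlap({k: up_sets[k] for k in take}).to_json_dict(),
            "down": setops.overlap({k: down_sets[k] for k in take}).to_json_dict(),
        }
        with open(out_dir / "overlap.json", "w") as fh:
            json.dump(summary["overlaps"], fh, indent=2, sort_keys=True)

    panel = clustering.dysregulated_union(deg_tables)
    summary["n_dysregulated"] = len(panel)
    if panel and len(sheet.strains) >= 3:
        link = clustering.cluster_strains(matrix, sheet, panel)
        summary["clustering"] = link.to_json_dict()
        with open(out_dir / "linkage.json", "w") as fh:
            json.dump(link.to_json_dict(), fh, indent=2, sort_keys=True)

    pd.concat(ratio_rows, ignore_index=True).to_csv(
        out_dir / "ratios.tsv", sep="\t", index=False
    )
    with open(out_dir / "peaks.json", "w") as fh:
        json.dump(peaks_json, fh, indent=2, sort_keys=True)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
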
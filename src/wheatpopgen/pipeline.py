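"""End-to-end orchestration: QC -> diversity -> LD -> thinning -> structure
-> distance/tree/PCoA, driven by a declarative YAML config.

The analysis runs each era group (landraces, modern cultivars) separately
through filtering, diversity and LD, then thins the common polymorphic
markers at the per-chromosome LD-decay spacing and runs the joint
structure pre-pass and the distance-based analyses on that thinned set.
Completed stages leave their artifacts plus a ``<stage>.done`` sentinel in
the output directory and are reused on re-run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, distance, ld, qc, structure
from .io import (GeneticMap, GenotypeMatrix, read_genetic_map,
                 read_genotype_matrix, read_sample_metadata,
                 write_genotype_matrix, write_newick)

logger = logging.getLogger("wheatpopgen")

STAGES = ("qc", "diversity", "ld", "thin", "structure", "distance")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    genotypes: str
    genetic_map: str
    output_dir: str
    metadata: str | None = None
    genotype_dialect: str = "matrix"
    max_missing: float = 0.25
    min_maf: float = 0.05
    ld_window_cM: float = 50.0
    ld_alpha: float = 0.001
    loess_span: float = 0.5
    default_decay_cM: float = 1.0      # thinning fallback when decay undefined
    k_min: int = 1
    k_max: int = 10
    replicates: int = 7
    burn_in: int = 10_000
    iterations: int = 100_000
    seed: int = 1
    strong_q: float = 0.7
    moderate_q: float = 0.5
    pcoa_axes: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.max_missing < 1 and 0 < self.min_maf < 1):
            raise ValueError("filter thresholds must lie in (0, 1)")
        if self.k_max < self.k_min or self.k_min < 1:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.replicates < 2:
            raise ValueError("Evanno needs >= 2 replicates")
        if self.k_max - self.k_min < 2:
            raise ValueError("Evanno needs >= 3 consecutive K values")
        if not (0 < self.moderate_q < self.strong_q < 1):
            raise ValueError("need 0 < moderate_q < strong_q < 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Handles to the per-stage artifacts of a completed run."""

    outdir: Path
    era_reports: dict = field(default_factory=dict)
    partition: qc.PolymorphismPartition | None = None
    decay: dict = field(default_factory=dict)
    thinned_loci: list[str] = field(default_factory=list)
    evanno: dict = field(default_factory=dict)


def _done(outdir: Path, stage: str) -> Path:
    return outdir / f"{stage}.done"


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    status = {"stages": {}, "failed": None}
    result = PipelineResult(outdir=outdir)
    try:
        gm, gmap, eras = _load(config)
        _stage_qc(config, outdir, gm, eras, status, result)
        _stage_diversity(config, outdir, gmap, status, result)
        _stage_ld(config, outdir, gmap, status, result)
        _stage_thin(config, outdir, gm, gmap, eras, status, result)
        _stage_structure(config, outdir, gm, eras, status, result)
        _stage_distance(config, outdir, gm, status, result)
    except Exception as exc:
        stage = next((s for s in STAGES if status["stages"].get(s) is None), "?")
        status["failed"] = {"stage": stage, "error": str(exc)}
        (outdir / "status.json").write_text(json.dumps(status, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    (outdir / "status.json").write_text(json.dumps(status, indent=2))
    return result


def _load(config: PipelineConfig):
    gm = read_genotype_matrix(config.genotypes, config.genotype_dialect)
    gmap = read_genetic_map(config.genetic_map, gm)
    if config.metadata is not None:
        meta = read_sample_metadata(config.metadata)
        gm.era_labels = meta.era_for(gm.sample_ids)
    if gm.era_labels is None:
        raise ValueError("era labels required: give metadata or an era column")
    eras = sorted(set(gm.era_labels.tolist()))
    if len(eras) != 2:
        raise ValueError(f"expected 2 era classes, found {eras}")
    return gm, gmap, eras


def _stage_qc(config, outdir, gm, eras, status, result):
    stage = "qc"
    if not _done(outdir, stage).exists():
        for era in eras:
            sub = gm.subset_samples(gm.era_labels == era)
            filtered, report = qc.filter_markers(sub, config.max_missing,
                                                 config.min_maf)
            write_genotype_matrix(filtered, outdir / f"filtered_{era}.tsv")
            pd.DataFrame([{
                "era": era,
                "n_input": report.n_input,
                "n_removed_missing": report.n_removed_missing,
                "n_removed_maf": report.n_removed_maf,
                "n_retained": report.n_retained,
            }]).to_csv(outdir / f"filter_report_{era}.tsv", sep="\t", index=False)
        part = qc.partition_polymorphism(gm, gm.era_labels)
        pd.DataFrame([asdict_part(part, eras)]).to_csv(
            outdir / "polymorphism_partition.tsv", sep="\t", index=False)
        _done(outdir, stage).touch()
    result.partition = _read_partition(outdir)
    for era in eras:
        result.era_reports[era] = pd.read_csv(
            outdir / f"filter_report_{era}.tsv", sep="\t")
    status["stages"][stage] = "ok"


def asdict_part(part: qc.PolymorphismPartition, eras) -> dict:
    return {
        "n_total_union": part.n_total_union,
        "n_common": part.n_common,
        f"n_only_{eras[0]}": part.n_only_group1,
        f"n_only_{eras[1]}": part.n_only_group2,
    }


def _read_partition(outdir: Path) -> qc.PolymorphismPartition:
    row = pd.read_csv(outdir / "polymorphism_partition.tsv", sep="\t").iloc[0]
    only = [c for c in row.index if c.startswith("n_only_")]
    return qc.PolymorphismPartition(
        int(row["n_total_union"]), int(row["n_common"]),
        int(row[only[0]]), int(row[only[1]]))


def _era_panels(config, outdir, eras) -> dict[str, GenotypeMatrix]:
    return {era: read_genotype_matrix(outdir / f"filtered_{era}.tsv")
            for era in eras}


def _stage_diversity(config, outdir, gmap, status, result):
    stage = "diversity"
    eras = list(result.era_reports)
    if not _done(outdir, stage).exists():
        panels = _era_panels(config, outdir, eras)
        for era, panel in panels.items():
            tbl = diversity.summarize_by_region(panel, gmap)
            tbl.to_csv(outdir / f"diversity_{era}.tsv", sep="\t", index=False)
        _done(outdir, stage).touch()
    status["stages"][stage] = "ok"


def _stage_ld(config, outdir, gmap, status, result):
    stage = "ld"
    eras = list(result.era_reports)
    if not _done(outdir, stage).exists():
        panels = _era_panels(config, outdir, eras)
        for era, panel in panels.items():
            table, _ = ld.ld_scan(panel, gmap, config.ld_window_cM,
                                  config.ld_alpha)
            table.to_csv(outdir / f"ld_table_{era}.tsv", sep="\t", index=False)
            crit = ld.critical_r2_per_genome(table)
            fits = []
            for chrom in sorted(table["chromosome"].unique()):
                c = crit.get(chrom[-1])
                if c is None:
                    continue
                fits.append(ld.fit_ld_decay(table, chrom, c,
                                            config.loess_span, config.ld_alpha))
            ld.decay_table(fits).to_csv(outdir / f"ld_decay_{era}.tsv",
                                        sep="\t", index=False)
        _done(outdir, stage).touch()
    for era in eras:
        result.decay[era] = pd.read_csv(outdir / f"ld_decay_{era}.tsv", sep="\t")
    status["stages"][stage] = "ok"


def _stage_thin(config, outdir, gm, gmap, eras, status, result):
    stage = "thin"
    path = outdir / "thinned_loci.txt"
    if not _done(outdir, stage).exists():
        panels = _era_panels(config, outdir, eras)
        common = (set(panels[eras[0]].locus_ids)
                  & set(panels[eras[1]].locus_ids))
        # per-chromosome decay = max over eras; fallback where undefined
        decay: dict[str, float] = {}
        for chrom in gmap.chromosomes():
            vals = []
            for era in eras:
                t = result.decay[era]
                row = t[t["chromosome"] == chrom]
                if len(row) and np.isfinite(row["decay_cM"].iloc[0]):
                    vals.append(float(row["decay_cM"].iloc[0]))
            decay[chrom] = max(vals) if vals else config.default_decay_cM
        sub = gm.subset_loci([l for l in gm.locus_ids if l in common])
        thinned = qc.thin_by_decay(sub, gmap, decay)
        path.write_text("\n".join(thinned) + "\n")
        _done(outdir, stage).touch()
    result.thinned_loci = path.read_text().split()
    status["stages"][stage] = "ok"


def _structure_one(config, outdir, tag, panel):
    k_values = list(range(config.k_min, config.k_max + 1))
    runs = structure.run_k_grid(
        panel, k_values, n_reps=config.replicates, burn_in=config.burn_in,
        iterations=config.iterations, master_seed=config.seed)
    lnp_rows = [{"K": K, "rep": i, "lnP": r.lnP_data}
                for K, rs in runs.items() for i, r in enumerate(rs)]
    pd.DataFrame(lnp_rows).to_csv(outdir / f"lnp_{tag}.tsv", sep="\t",
                                  index=False)
    ev = structure.evanno_delta_k(
        {K: [r.lnP_data for r in rs] for K, rs in runs.items()})
    ev.table.to_csv(outdir / f"evanno_{tag}.tsv", sep="\t", index=False)
    best = ev.best_K if ev.best_K is not None else config.k_min + 1
    q_mean = structure.aggregate_runs(runs[best])
    members = structure.assign_membership(q_mean, panel.sample_ids,
                                          config.strong_q, config.moderate_q)
    q_cols = pd.DataFrame(q_mean, columns=[f"q{SP+1}" for SP in range(best)])
    pd.concat([members, q_cols], axis=1).to_csv(
        outdir / f"structure_{tag}.tsv", sep="\t", index=False)
    return ev


def _stage_structure(config, outdir, gm, eras, status, result):
    stage = "structure"
    if not _done(outdir, stage).exists():
        thin_gm = gm.subset_loci(result.thinned_loci)
        # joint pre-pass over the whole collection on the thinned common set
        _structure_one(config, outdir, "joint", thin_gm)
        for era in eras:
            panel = thin_gm.subset_samples(thin_gm.era_labels == era)
            _structure_one(config, outdir, era, panel)
        _done(outdir, stage).touch()
    for tag in ["joint"] + list(eras):
        result.evanno[tag] = pd.read_csv(outdir / f"evanno_{tag}.tsv", sep="\t")
    status["stages"][stage] = "ok"


def _stage_distance(config, outdir, gm, status, result):
    stage = "distance"
    if not _done(outdir, stage).exists():
        thin_gm = gm.subset_loci(result.thinned_loci)
        dm = distance.simple_matching_distance(thin_gm)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            outdir / "distance_matrix.tsv", sep="\t")
        tree = distance.neighbor_joining(dm)
        write_newick(tree, outdir / "nj_tree.nwk")
        res = distance.pcoa(dm, n_axes=config.pcoa_axes)
        coords = pd.DataFrame(
            res.coordinates, index=res.sample_ids,
            columns=[f"PCo{i+1}" for i in range(res.coordinates.shape[1])])
        coords.insert(0, "sample_id", coords.index)
        coords.to_csv(outdir / "pcoa_coordinates.tsv", sep="\t", index=False)
        pd.DataFrame({
            "axis": np.arange(1, len(res.eigenvalues) + 1),
            "eigenvalue": res.eigenvalues,
            "proportion": res.proportion_explained,
        }).to_csv(outdir / "pcoa_eigenvalues.tsv", sep="\t", index=False)
        _done(outdir, stage).touch()
    status["stages"][stage] = "ok"
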
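"""Pipeline configuration and stage orchestration.

A :class:`PipelineConfig` holds the stage selection and every fixed
threshold of the analysis (taxonomic majority vote 0.90; merge rules
0.40/0.50; cluster-scan e-value cutoffs 1e-20 and relaxed 1e-10;
self-synteny thresholds 1e-5 and 1e-60; repeat-read cutoffs 0.50/0.25),
with defaults equal to the standard values used throughout the package.
:func:`run_pipeline` executes the selected stages in order
(simulate -> decontam -> merge-annot -> self-synteny), logging seeds,
thresholds and input digests into a machine-readable JSON run report.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from . import annotweave, decontam, selfsynteny, simdata
from . import formats_io as fio
from .core import AssemblyLayout

ALL_STAGES = ("simulate", "decontam", "merge-annot", "self-synteny")


@dataclass
class PipelineConfig:
    workdir: str = "oxgrid_run"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    scenario: str = "wgd"  # "wgd" | "tandem" | "none"
    sim: simdata.SimConfig = field(default_factory=simdata.SimConfig)
    min_metazoan: float = decontam.DEFAULT_MIN_METAZOAN
    min_containment: float = annotweave.DEFAULT_MIN_CONTAINMENT
    min_mean_overlap: float = annotweave.DEFAULT_MIN_MEAN_OVERLAP
    evalue_cutoff: float = 1e-20
    relaxed_evalue_cutoff: float = 1e-10
    selfsyn_thresholds: list[float] = field(default_factory=lambda: list(selfsynteny.DEFAULT_THRESHOLDS))
    repeat_high_cutoff: float = decontam.HIGH_REPEAT_CUTOFF
    repeat_mild_cutoff: float = decontam.MILD_REPEAT_CUTOFF
    min_cell: float = 5.0
    norm_mode: str = "caption"

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {ALL_STAGES}")
        if self.scenario not in ("wgd", "tandem", "none"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("min_metazoan", "min_containment", "min_mean_overlap",
                     "repeat_high_cutoff", "repeat_mild_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("evalue_cutoff", "relaxed_evalue_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.selfsyn_thresholds:
            raise ValueError("selfsyn_thresholds must be non-empty")
        if self.norm_mode not in ("caption", "donor"):
            raise ValueError("norm_mode must be 'caption' or 'donor'")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        noise_raw = sim_raw.pop("evidence_noise", {}) if isinstance(sim_raw, dict) else {}
        sim = simdata.SimConfig(**sim_raw, evidence_noise=simdata.EvidenceNoise(**noise_raw))
        cfg = cls(**raw, sim=sim)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_to_dir(config: PipelineConfig, outdir: Path) -> dict:
    """Run the simulator and write every evidence file to ``outdir``."""
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    genome = simdata.simulate_base_genome(sim)
    if config.scenario == "wgd":
        genome, truth = simdata.apply_wgd(genome, sim.wgd_retention, sim.seed + 1)
    elif config.scenario == "tandem":
        genome, truth = simdata.apply_tandem(genome, sim.tandem_rate, sim.tandem_max_copies, sim.seed + 1)
    else:
        truth = simdata.TruthTable()
    truth.check_consistency(genome)

    fio.write_layout_tsv(genome.layout, outdir / "layout.tsv")
    fio.write_gff3(genome, outdir / "genes.gff3")
    hits = simdata.emit_self_hits(genome, truth, sim.wgd_detectability, sim.spurious_hit_rate, sim.seed + 2)
    fio.write_hits_table(hits, outdir / "self_hits.tsv")
    clusters, r1, r2, denovo = simdata.emit_annotation_evidence(genome, sim.evidence_noise, sim.seed + 3)
    fio.write_clusters_gff3(clusters, genome.layout, outdir / "clusters.gff3")
    from .core import AnnotationSet

    fio.write_gff3(AnnotationSet(genome.layout, r1), outdir / "models_r1.gff3")
    fio.write_gff3(AnnotationSet(genome.layout, r2), outdir / "models_r2.gff3")
    for stage, models in denovo.items():
        fio.write_gff3(AnnotationSet(genome.layout, models), outdir / f"denovo_{stage}.gff3")
    tax, contaminants = simdata.emit_tax_hits(
        genome, sim.contaminant_fraction, sim.hits_per_scaffold,
        sim.metazoan_fraction_clean, sim.metazoan_fraction_contam, sim.seed + 4,
    )
    fio.write_tax_hits(tax, outdir / "tax_hits.tsv")
    profiles = simdata.emit_read_repeat_profiles(2_000, ("uniform", 0.0, 1.0), sim.seed + 5)
    fio.write_read_profiles(profiles, outdir / "read_profiles.tsv")
    with open(outdir / "truth_pairs.tsv", "w") as fh:
        for (a, b), origin in sorted(truth.paralog_pairs.items()):
            fh.write(f"{a}\t{b}\t{origin}\n")
    (outdir / "truth_contaminants.txt").write_text("".join(s + "\n" for s in sorted(contaminants)))
    return {
        "n_chromosomes": len(genome.layout),
        "n_genes": len(genome),
        "n_truth_pairs": len(truth.paralog_pairs),
        "n_self_hit_rows": int(len(hits)),
        "n_clusters": len(clusters),
        "n_models_r1": len(r1),
        "n_models_r2": len(r2),
        "n_denovo_mappings": sum(len(v) for v in denovo.values()),
        "n_truth_contaminants": len(contaminants),
    }


def run_pipeline(config: PipelineConfig, report_path: Optional[Path] = None) -> dict:
    """Execute the selected stages in order; return (and write) the run report."""
    config.validate()
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    simdir = workdir / "sim"
    report: dict = {
        "tool": "oxgrid",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
    }

    if "simulate" in config.stages:
        report["stages"]["simulate"] = simulate_to_dir(config, simdir)

    required = [simdir / "layout.tsv", simdir / "genes.gff3"]
    for p in required:
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline input {p} (run the simulate stage or provide data)")
    layout = fio.read_layout_tsv(simdir / "layout.tsv")
    report["inputs"] = {
        str(p.relative_to(workdir)): _digest(p) for p in sorted(simdir.glob("*")) if p.is_file()
    }

    if "decontam" in config.stages:
        tax = fio.read_tax_hits(simdir / "tax_hits.tsv")
        keep, remove, renaming = decontam.decontaminate(
            tax, list(layout.names), config.min_metazoan
        )
        profiles = fio.read_read_profiles(simdir / "read_profiles.tsv")
        classes = decontam.classify_repeat_reads(
            profiles, config.repeat_high_cutoff, config.repeat_mild_cutoff
        )
        outdir = workdir / "decontam"
        outdir.mkdir(exist_ok=True)
        (outdir / "keep.txt").write_text("".join(s + "\n" for s in keep))
        (outdir / "remove.txt").write_text("".join(s + "\n" for s in remove))
        with open(outdir / "renaming.tsv", "w") as fh:
            for old, new in renaming.items():
                fh.write(f"{old}\t{new}\n")
        report["stages"]["decontam"] = {
            "n_kept": len(keep),
            "n_removed": len(remove),
            "removed": remove,
            "read_classes": classes,
        }

    annotation = None
    if "merge-annot" in config.stages:
        clusters = fio.read_clusters_gff3(simdir / "clusters.gff3")
        r1 = list(fio.read_gff3(simdir / "models_r1.gff3", layout))
        annotation, _ = annotweave.reconcile_round1(
            r1, clusters, layout, config.min_containment, config.min_mean_overlap
        )
        n_round1 = len(annotation)
        r2_path = simdir / "models_r2.gff3"
        added_r2: list[str] = []
        if r2_path.exists():
            r2 = list(fio.read_gff3(r2_path, layout))
            annotation, added_r2 = annotweave.incorporate_novel_models(annotation, r2, "r2_")
        stage_maps = {}
        for p in sorted(simdir.glob("denovo_*.gff3")):
            stage_maps[p.stem.replace("denovo_", "")] = list(fio.read_gff3(p, layout))
        added_dn: list[str] = []
        if stage_maps:
            anchor = simdata.ANCHOR_STAGE if simdata.ANCHOR_STAGE in stage_maps else sorted(stage_maps)[0]
            annotation, added_dn = annotweave.reconcile_denovo(annotation, stage_maps, anchor)
        genes, by_source = annotweave.finalize_annotation(annotation)
        fio.write_gff3(annotation, workdir / "merged.gff3")
        report["stages"]["merge-annot"] = {
            "n_round1": n_round1,
            "n_round2_added": len(added_r2),
            "n_denovo_added": len(added_dn),
            "n_total": len(genes),
            "by_source": by_source,
        }

    if "self-synteny" in config.stages:
        hits = fio.read_hits_table(simdir / "self_hits.tsv")
        truth_genome = fio.read_gff3(simdir / "genes.gff3", layout)
        positions = selfsynteny.positions_from_annotation(truth_genome)
        gene_counts = truth_genome.genes_per_chromosome()
        outdir = workdir / "selfsynteny"
        outdir.mkdir(exist_ok=True)
        stage_report = {}
        for t in config.selfsyn_thresholds:
            pairs = selfsynteny.filter_self_hits(
                hits, simdata.transcript_to_gene, positions, t
            )
            grid = selfsynteny.build_oxford_grid(pairs, positions, layout)
            matrix = selfsynteny.contribution_matrix(
                pairs, gene_counts, list(layout.names), config.norm_mode
            )
            summary = selfsynteny.summarize_contributions(matrix)
            partners, matching = selfsynteny.score_duplication_signal(matrix, config.min_cell)
            tag = f"{t:.0e}"
            grid.to_csv(outdir / f"grid_{tag}.tsv", sep="\t", index=False)
            matrix.to_csv(outdir / f"matrix_{tag}.tsv", sep="\t")
            stage_report[tag] = {
                "n_pairs": int(len(pairs)),
                "summary": summary,
                "n_partner_calls": sum(1 for p in partners.values() if p is not None),
                "mutual_best_pairs": [list(m) for m in matching],
            }
        report["stages"]["self-synteny"] = stage_report

    if report_path is None:
        report_path = workdir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report
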
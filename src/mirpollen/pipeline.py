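"""End-to-end orchestration with file-based stage boundaries.

Every stage consumes and produces plain files (FASTA/GFF3/SAM/FASTQ/TSV),
so any stage can run standalone on externally produced data (aligner SAM
output, imported prediction or differential-expression tables).  ``run``
executes the stages in dependency order on a self-contained synthetic
dataset, emitting per-stage telescoping reports and a reproducible run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import (
    annotation_io,
    degradome_validation,
    expression_integration,
    family_assignment,
    mirna_discovery,
    synthetic_data,
    target_prediction,
    utr_extension,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 1
    preset: str = "default"
    outdir: str = "mirpollen_run"
    # discovery thresholds
    min_len: int = 18
    max_len: int = 24
    min_abundance: int = 2
    mfe_threshold: float = -35.0
    hairpin_coverage: float = 0.75
    min_loop: int = 4
    max_loci: int = 20
    strict_loop: bool = False
    # extension
    min_depth: int = 1
    adjacency_gap: int = 0
    # targets
    max_expectation: float = 3.0
    max_targets: int = 500
    # integration
    alpha: float = 0.05
    min_lfc: float = 0.0
    # degradome
    flank: int = 4
    folding_backend: str = "builtin"


_RANGES = {
    "min_len": (10, 30),
    "max_len": (10, 40),
    "min_abundance": (1, 1000),
    "hairpin_coverage": (0.0, 1.0),
    "min_loop": (1, 50),
    "max_loci": (1, 1000),
    "min_depth": (1, 10**6),
    "adjacency_gap": (0, 10**4),
    "max_expectation": (0.0, 10.0),
    "max_targets": (1, 10**6),
    "alpha": (0.0, 1.0),
    "flank": (0, 50),
}


def validate_config(path_or_mapping) -> RunConfig:
    """Build a validated RunConfig from a YAML file or mapping.

    Defaults are injected for absent keys; unknown keys are rejected;
    string-typed numbers are coerced with a warning; all range
    violations are reported together.
    """
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_mapping or {})
    known = {f.name: f.type for f in fields(RunConfig)}
    errors = []
    clean = {}
    for key, value in raw.items():
        if key not in known:
            errors.append(f"unknown configuration key {key!r}")
            continue
        default = getattr(RunConfig(), key)
        if isinstance(default, bool):
            value = bool(value)
        elif isinstance(default, int) and not isinstance(value, bool):
            if isinstance(value, str):
                log.warning("coercing %s=%r to int", key, value)
            try:
                value = int(value)
            except (TypeError, ValueError):
                errors.append(f"{key}: cannot interpret {value!r} as integer")
                continue
        elif isinstance(default, float):
            if isinstance(value, str):
                log.warning("coercing %s=%r to float", key, value)
            try:
                value = float(value)
            except (TypeError, ValueError):
                errors.append(f"{key}: cannot interpret {value!r} as number")
                continue
        clean[key] = value
    for key, (lo, hi) in _RANGES.items():
        if key in clean and not (lo <= clean[key] <= hi):
            errors.append(f"{key}: {clean[key]} outside [{lo}, {hi}]")
    if clean.get("preset", "default") not in ("tiny", "default", "stress"):
        errors.append(f"preset: {clean.get('preset')!r} not one of tiny/default/stress")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(**clean)


@dataclass
class StageReport:
    stage: str
    counts: dict[str, int] = field(default_factory=dict)
    wall_time: float = 0.0
    parameters: dict = field(default_factory=dict)


class PipelineRun:
    """Holds stage outputs and reports for one orchestrated run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.reports: list[StageReport] = []
        self.artifacts: dict[str, object] = {}

    def _report(self, stage: str, counts: dict[str, int], t0: float, **params):
        rep = StageReport(stage, counts, time.time() - t0, params)
        self.reports.append(rep)
        log.info("stage %s: %s (%.1fs)", stage, counts, rep.wall_time)
        return rep

    # ------------------------------------------------------------------
    def stage_simulate(self) -> None:
        t0 = time.time()
        cfg = synthetic_data.preset_config(self.config.preset, self.config.seed)
        genome, true_models, trunc_models, truth_ann = (
            synthetic_data.simulate_genome_annotation(cfg)
        )
        exonic_pool = []
        for m in true_models[:4]:
            cdna = annotation_io.extract_transcript_sequence(m, genome)
            exonic_pool.append(cdna[50:71])
        genome, sr_libs, contaminants, truth_hp = (
            synthetic_data.simulate_hairpins_smallrna(genome, cfg, exonic_pool)
        )
        matures = [h.mature_sequence for h in truth_hp.hairpins]
        truncated_tids = {
            tid for tid, d in truth_ann.truncated.items() if d > 0
        }
        genome, truth_sites = synthetic_data.plant_target_sites(
            genome, true_models, truncated_tids, matures, cfg
        )
        mace = synthetic_data.simulate_mace_reads(genome, true_models, cfg)

        d = self.outdir
        annotation_io.write_fasta(genome, str(d / "genome.fa"))
        annotation_io.write_annotation(true_models, str(d / "annotation_true.gff3"))
        annotation_io.write_annotation(trunc_models, str(d / "annotation_current.gff3"))
        (d / "mace").mkdir(exist_ok=True)
        for lib, recs in mace.items():
            synthetic_data.write_sam(recs, genome, str(d / "mace" / f"{lib}.sam"))
        (d / "smallrna").mkdir(exist_ok=True)
        for lib, reads in sr_libs.items():
            synthetic_data.write_fastq(reads, str(d / "smallrna" / f"{lib}.fastq"))
        with open(d / "contaminants.fa", "w") as fh:
            for i, (seq, rtype) in enumerate(contaminants):
                fh.write(f">contam{i} type={rtype}\n{seq}\n")
        pd.DataFrame(
            [
                {"library": lib, "stage": s, "condition": c, "replicate": r}
                for lib, (s, c, r) in cfg.libraries.items()
            ]
        ).to_csv(d / "design.tsv", sep="\t", index=False)

        # synthetic functional-term table (level-2 ontology style), the
        # stand-in for an externally produced annotation mapping
        terms = [
            "RNA.regulation of transcription", "protein.degradation",
            "stress.abiotic", "signalling.receptor kinases",
            "development.unspecified", "cell.organisation",
        ]
        rng = __import__("numpy").random.default_rng(cfg.seed + 6)
        term_map = {}
        for m in true_models:
            k = 1 + int(rng.random() < 0.25)
            term_map[m.transcript_id] = list(
                rng.choice(terms, size=k, replace=False)
            )
        pd.DataFrame(
            [
                {"feature_id": tid, "level2_term": t}
                for tid, ts in term_map.items() for t in ts
            ]
        ).to_csv(d / "term_map.tsv", sep="\t", index=False)
        self.artifacts["term_map"] = term_map

        self.artifacts.update(
            sim_config=cfg, genome=genome, true_models=true_models,
            trunc_models=trunc_models, truth_ann=truth_ann,
            truth_hp=truth_hp, truth_sites=truth_sites,
            smallrna=sr_libs, contaminants=contaminants, mace=mace,
        )
        self._report(
            "simulate",
            {
                "genes": len(true_models),
                "hairpins": len(truth_hp.hairpins),
                "libraries": len(cfg.libraries),
                "planted_sites": len(truth_sites),
            },
            t0, preset=self.config.preset, seed=self.config.seed,
        )

    # ------------------------------------------------------------------
    def stage_extend(self) -> None:
        t0 = time.time()
        genome = self.artifacts["genome"]
        models = self.artifacts["trunc_models"]
        reads = []
        for lib, recs in self.artifacts["mace"].items():
            for rid, chrom, strand, blocks, seq in recs:
                reads.append(
                    annotation_io.AlignedRead(
                        rid, seq, chrom, strand,
                        tuple(
                            annotation_io.GenomicInterval(chrom, s, e, strand)
                            for s, e in blocks
                        ),
                    )
                )
        results, extended = utr_extension.extend_annotation(
            reads, models, genome,
            min_depth=self.config.min_depth,
            adjacency_gap=self.config.adjacency_gap,
        )
        annotation_io.write_annotation(
            extended, str(self.outdir / "annotation_extended.gff3")
        )
        rows = [
            {
                "transcript_id": r.transcript_id,
                "old_end": r.old_end,
                "new_end": r.new_end,
                "category": r.category,
                "delta_utr3": r.utr3_length_after - r.utr3_length_before,
            }
            for r in results.values()
        ]
        pd.DataFrame(rows).to_csv(
            self.outdir / "extension_report.tsv", sep="\t", index=False
        )
        self.artifacts.update(extension_results=results, extended_models=extended)
        cats = pd.Series([r.category for r in results.values()]).value_counts()
        self._report(
            "extend",
            {"transcripts": len(results), "extended": int((cats.drop("none", errors="ignore")).sum())},
            t0, min_depth=self.config.min_depth,
        )

    # ------------------------------------------------------------------
    def stage_discover(self) -> None:
        t0 = time.time()
        cfg = self.artifacts["sim_config"]
        records, report = mirna_discovery.discover_mirnas(
            self.artifacts["smallrna"],
            self.artifacts["genome"],
            self.artifacts["extended_models"],
            cfg.libraries,
            contaminants=self.artifacts["contaminants"],
            mfe_threshold=self.config.mfe_threshold,
            min_len=self.config.min_len,
            max_len=self.config.max_len,
            min_abundance=self.config.min_abundance,
            max_loci=self.config.max_loci,
            min_coverage=self.config.hairpin_coverage,
            min_loop=self.config.min_loop,
            strict_loop=self.config.strict_loop,
            backend=self.config.folding_backend,
        )
        annotation_io.write_fasta(
            {r.name: r.sequence for r in records},
            str(self.outdir / "mirnas.fa"),
        )
        rows = []
        for r in records:
            for iv in r.loci:
                rows.append(
                    {
                        "miRNA": r.name, "sequence": r.sequence,
                        "chrom": iv.chrom, "start": iv.start + 1,
                        "end": iv.end, "strand": iv.strand,
                    }
                )
        pd.DataFrame(rows).to_csv(self.outdir / "mirna_loci.tsv", sep="\t", index=False)
        self.artifacts["mirnas"] = records
        self._report("discover", report.as_dict(), t0,
                     mfe_threshold=self.config.mfe_threshold)

    # ------------------------------------------------------------------
    def stage_family(self) -> None:
        t0 = time.time()
        truth_hp = self.artifacts["truth_hp"]
        genome = self.artifacts["genome"]
        # synthetic hairpin reference built from the planted precursors
        hairpin_fasta = {}
        mature_rows = []
        for i, h in enumerate(truth_hp.hairpins):
            hid = f"syn-MIR{i + 1:03d}"
            hairpin_fasta[hid] = genome[h.chrom][h.start : h.end]
            m0 = h.mature_interval.start - h.start
            mature_rows.append((hid, f"{hid}-mat", m0 + 1, m0 + len(h.mature_sequence)))
        reference = family_assignment.load_hairpin_reference(
            hairpin_fasta, mature_rows
        )
        assignments = family_assignment.assign_families(
            [(r.name, r.sequence) for r in self.artifacts["mirnas"]], reference
        )
        pd.DataFrame(
            [
                {
                    "miRNA": a.mirna,
                    "family": a.family or "",
                    "category": a.category,
                    "best_hairpin": a.best_hits[0].hairpin_id if a.best_hits else "",
                }
                for a in assignments
            ]
        ).to_csv(self.outdir / "families.tsv", sep="\t", index=False)
        self.artifacts["families"] = assignments
        counts = pd.Series([a.category for a in assignments]).value_counts().to_dict()
        self._report(
            "family",
            {"mirnas": len(assignments), **{f"category_{k}": v for k, v in counts.items()}},
            t0,
        )

    # ------------------------------------------------------------------
    def stage_targets(self) -> None:
        t0 = time.time()
        genome = self.artifacts["genome"]
        extended = self.artifacts["extended_models"]
        cdnas = {
            m.transcript_id: annotation_io.extract_transcript_sequence(m, genome)
            for m in extended
        }
        mirnas = {r.name: r.sequence for r in self.artifacts["mirnas"]}
        sites = target_prediction.predict_targets(
            mirnas, cdnas,
            max_expectation=self.config.max_expectation,
            max_targets=self.config.max_targets,
        )
        by_id = {m.transcript_id: m for m in extended}
        for s in sites:
            target_prediction.annotate_site_region(s, by_id[s.transcript_id])
        target_prediction.export_prediction_table(
            sites, str(self.outdir / "target_sites.tsv")
        )
        self.artifacts.update(target_sites=sites, cdnas=cdnas)
        regions = pd.Series([s.region for s in sites]).value_counts().to_dict()
        self._report(
            "targets",
            {"sites": len(sites), **{f"region_{k}": v for k, v in regions.items()}},
            t0, max_expectation=self.config.max_expectation,
        )

    # ------------------------------------------------------------------
    def stage_integrate(self) -> None:
        t0 = time.time()
        cfg = self.artifacts["sim_config"]
        sites = self.artifacts["target_sites"]
        mrna_features = sorted({m.transcript_id for m in self.artifacts["extended_models"]})
        mirna_features = sorted({r.name for r in self.artifacts["mirnas"]})
        pairs = sorted({(s.mirna, s.transcript_id) for s in sites})
        cm_mrna, cm_mirna, truth_de = synthetic_data.simulate_counts(
            mrna_features, mirna_features, pairs, cfg
        )
        contrast_name = next(iter(truth_de.de_effects))[1] if truth_de.de_effects else (
            f"{cfg.stages[min(1, len(cfg.stages) - 1)]}_vs_{cfg.stages[0]}"
        )
        contrast = (
            (cfg.stages[min(1, len(cfg.stages) - 1)], cfg.conditions[0]),
            (cfg.stages[0], cfg.conditions[0]),
        )
        de_mrna = expression_integration.differential_test(
            cm_mrna, contrast, contrast_name, self.config.alpha
        )
        de_mirna = expression_integration.differential_test(
            cm_mirna, contrast, contrast_name, self.config.alpha
        )
        inverse = expression_integration.find_inverse_pairs(
            de_mirna, de_mrna, sites, self.config.alpha, self.config.min_lfc
        )
        cm_mrna.counts.to_csv(self.outdir / "counts_mrna.tsv", sep="\t")
        cm_mirna.counts.to_csv(self.outdir / "counts_mirna.tsv", sep="\t")
        pd.DataFrame(
            [
                {
                    "miRNA": p.mirna, "transcript": p.transcript,
                    "contrast": p.contrast, "direction": p.direction,
                    "regions": ",".join(p.regions),
                }
                for p in inverse
            ]
        ).to_csv(self.outdir / "inverse_pairs.tsv", sep="\t", index=False)
        expression_integration.write_network(
            inverse, str(self.outdir / "network.gml")
        )
        term_summary = expression_integration.summarize_functional(
            inverse, self.artifacts.get("term_map", {})
        )
        term_summary.to_csv(self.outdir / "term_summary.tsv", sep="\t", index=False)
        self.artifacts.update(
            inverse_pairs=inverse, truth_de=truth_de,
            de_mrna=de_mrna, de_mirna=de_mirna,
        )
        self._report(
            "integrate",
            {
                "planted_pairs": len(truth_de.inverse_pairs),
                "detected_pairs": len(inverse),
            },
            t0, alpha=self.config.alpha,
        )

    # ------------------------------------------------------------------
    def stage_degradome(self) -> None:
        t0 = time.time()
        cfg = self.artifacts["sim_config"]
        genome = self.artifacts["genome"]
        true_models = self.artifacts["true_models"]
        cdnas_true = {
            m.transcript_id: annotation_io.extract_transcript_sequence(m, genome)
            for m in true_models
        }
        truth_sites = self.artifacts["truth_sites"]
        records, truth_deg = synthetic_data.simulate_degradome(
            truth_sites, cdnas_true, cfg
        )
        seq_to_name = {r.sequence: r.name for r in self.artifacts["mirnas"]}
        predicted = self.artifacts["target_sites"]
        results = degradome_validation.verify_sites(
            predicted, self.artifacts["cdnas"], records, self.config.flank
        )
        degradome_validation.write_verification_table(
            results, str(self.outdir / "degradome_verification.tsv")
        )
        self.artifacts.update(
            degradome_records=records, degradome_results=results,
            truth_degradome=truth_deg, mature_to_name=seq_to_name,
        )
        self._report(
            "degradome",
            {
                "records": len(records),
                "comparisons": len(results),
                "verified": sum(1 for r in results if r.verified),
            },
            t0, flank=self.config.flank,
        )

    # ------------------------------------------------------------------
    def run(self) -> dict:
        order = [
            self.stage_simulate, self.stage_extend, self.stage_discover,
            self.stage_family, self.stage_targets, self.stage_integrate,
            self.stage_degradome,
        ]
        for stage_fn in order:
            try:
                stage_fn()
            except Exception as exc:
                log.error("stage %s failed: %s", stage_fn.__name__, exc)
                self._write_manifest(failed=stage_fn.__name__)
                raise
        return self._write_manifest()

    def _write_manifest(self, failed: str | None = None) -> dict:
        from . import __version__

        params = asdict(self.config)
        manifest = {
            "version": __version__,
            "seed": self.config.seed,
            "parameters": params,
            "parameter_hash": hashlib.sha256(
                json.dumps(params, sort_keys=True).encode()
            ).hexdigest()[:16],
            "failed_stage": failed,
            "stages": [
                {
                    "stage": r.stage,
                    "counts": r.counts,
                    "parameters": r.parameters,
                }
                for r in self.reports
            ],
        }
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def run(config: RunConfig) -> PipelineRun:
    """Run the full pipeline on a synthetic dataset; returns the run
    object with all stage artifacts and reports."""
    pr = PipelineRun(config)
    pr.run()
    return pr


__all__ = ["RunConfig", "StageReport", "PipelineRun", "run", "validate_config"]
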
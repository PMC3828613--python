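"""End-to-end orchestration of the analysis stages.

Order of stages: read QC → rRNA partition (with density profiles) →
genome-alignment intake → post-alignment filters → compartment assignment
→ coverage detection (cellular rule for the cellular sample, pooled rule
across the exosomal samples) → EM/RPKM quantification → consolidated
summaries. Each stage writes a TSV into the output directory and a
manifest records every stage output; a rerun with the same configuration
and seed reproduces identical files.
"""

from __future__ import annotations

import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import alnfilter, covdetect, quant, readqc, rrna, simdata, stats
from .annotation import read_gtf
from .seqio import read_fasta, read_fastq, write_fastq

logger = logging.getLogger("exorna")

STAGES = (
    "qc",
    "rrna_partition",
    "rrna_density",
    "filter_funnel",
    "compartments",
    "detection",
    "abundance",
    "summary",
)

CELLULAR = "cellular"
EXOSOMAL = "exosomal"


@dataclass
class SampleConfig:
    label: str
    role: str  # cellular | exosomal
    fastq: Optional[str] = None
    alignments: Optional[str] = None
    simulate: Optional[str] = None  # "exosome" | "cell" -> generate inputs


@dataclass
class PipelineConfig:
    output_dir: str
    samples: List[SampleConfig]
    rrna_fasta: Optional[str] = None
    annotation_gtf: Optional[str] = None
    genome_fasta: Optional[str] = None
    seed: int = 0
    n_reads: int = 20_000
    qc: readqc.QcParams = field(default_factory=readqc.QcParams)
    rrna_params: rrna.RrnaParams = field(default_factory=rrna.RrnaParams)
    min_aligned_len: int = 20
    min_mapq: int = 10
    em_tolerance: int = 0
    em_max_iter: int = 1000
    enrichment_table: Optional[str] = None
    enrichment_min_count: int = 5
    enrichment_ease: float = 0.1
    enrichment_q: float = 0.05

    @staticmethod
    def from_yaml(path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleConfig(**s) for s in raw.pop("samples")]
        qc = readqc.QcParams(**raw.pop("qc", {}))
        rp = rrna.RrnaParams(**raw.pop("rrna_params", {}))
        return PipelineConfig(samples=samples, qc=qc, rrna_params=rp, **raw)

    def validate(self) -> None:
        problems = []
        roles = [s.role for s in self.samples]
        if any(r not in (CELLULAR, EXOSOMAL) for r in roles):
            problems.append("sample roles must be 'cellular' or 'exosomal'")
        if roles.count(CELLULAR) > 1:
            problems.append("at most one cellular sample is allowed")
        simulated = any(s.simulate for s in self.samples)
        if not simulated:
            for name in ("rrna_fasta", "annotation_gtf"):
                if getattr(self, name) is None:
                    problems.append(f"missing required input: {name}")
                elif not os.path.exists(getattr(self, name)):
                    problems.append(f"{name} does not exist: {getattr(self, name)}")
            for s in self.samples:
                if s.fastq is None or s.alignments is None:
                    problems.append(
                        f"sample {s.label}: fastq and alignments are required "
                        "when not simulating"
                    )
        if self.enrichment_table and not os.path.exists(self.enrichment_table):
            problems.append(f"enrichment_table does not exist: {self.enrichment_table}")
        if problems:
            raise ValueError("invalid configuration: " + "; ".join(problems))


@dataclass
class ReportBundle:
    config: PipelineConfig
    tables: Dict[str, pd.DataFrame]
    manifest: Dict[str, object]


def _derive_seed(seed: int, salt: int) -> int:
    return (seed * 1_000_003 + salt) % (2**31 - 1)


def _simulate_sample(
    sample: SampleConfig, cfg: PipelineConfig, reference: simdata.ToyReference, outdir: str
) -> Tuple[str, str]:
    profile = (
        simdata.exosome_profile(cfg.n_reads)
        if sample.simulate == "exosome"
        else simdata.cell_profile(cfg.n_reads)
    )
    seed = _derive_seed(cfg.seed, zlib.crc32(sample.label.encode()) % 9973)
    reads, truths = simdata.simulate_library(profile, reference, seed)
    fq = os.path.join(outdir, f"{sample.label}.fastq")
    sam = os.path.join(outdir, f"{sample.label}.truth.sam")
    write_fastq(reads, fq)
    simdata.emit_truth_alignments(truths, reference, sam)
    simdata.write_truth_table(truths, os.path.join(outdir, f"{sample.label}.truth.tsv"))
    return fq, sam


def _write(df: pd.DataFrame, path: str) -> str:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages; returns the in-memory bundle after writing all
    stage outputs and the manifest under ``config.output_dir``."""
    config.validate()
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "pipeline.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest: Dict[str, object] = {"stages": {}, "failed": None, "seed": config.seed}
    tables: Dict[str, pd.DataFrame] = {}
    try:
        # ------------------------------------------------------------ inputs
        simulated = any(s.simulate for s in config.samples)
        if simulated:
            reference = simdata.build_reference(
                simdata.default_reference_spec(seed=_derive_seed(config.seed, 1))
            )
            paths = simdata.write_reference(reference, outdir)
            rrna_refs = reference.rrna
            models = reference.models
            manifest["reference"] = paths
        else:
            rrna_refs = read_fasta(config.rrna_fasta)
            models = read_gtf(config.annotation_gtf)

        sample_inputs: Dict[str, Tuple[str, str]] = {}
        for s in config.samples:
            if s.simulate:
                sample_inputs[s.label] = _simulate_sample(
                    s, config, reference, outdir
                )
            else:
                sample_inputs[s.label] = (s.fastq, s.alignments)

        index = rrna.RrnaIndex(rrna_refs, seed_len=config.rrna_params.seed_len)
        exon_index = alnfilter.build_exon_index(models)

        # --------------------------------------------------------- per sample
        qc_rows, part_rows, dens_rows, funnel_rows, comp_rows = [], [], [], [], []
        cov_rows: List[pd.DataFrame] = []
        calls: List[covdetect.DetectionCall] = []
        estimates: Dict[str, List[quant.AbundanceEstimate]] = {}
        kept_blocks: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
        detected_genes: Dict[str, pd.DataFrame] = {}

        exo_labels = [s.label for s in config.samples if s.role == EXOSOMAL]
        cell_label = next(
            (s.label for s in config.samples if s.role == CELLULAR), None
        )

        for s in config.samples:
            fq_path, aln_path = sample_inputs[s.label]
            raw_reads = read_fastq(fq_path)
            passed, qc_rep = readqc.process_reads(raw_reads, config.qc)
            logger.info("%s: QC %d -> %d reads", s.label, qc_rep.input_reads, qc_rep.passed)
            qc_rows.append({"sample": s.label, **qc_rep.__dict__})

            assigned, remainder = rrna.partition_library(
                passed, index, config.rrna_params
            )
            hits = [h for _, h in assigned]
            fracs = rrna.subunit_read_fractions(hits)
            part_rows.append(
                {
                    "sample": s.label,
                    "qc_passed": len(passed),
                    "rrna_reads": len(assigned),
                    "remainder_reads": len(remainder),
                    "rrna_fraction": len(assigned) / len(passed) if passed else 0.0,
                    **{f"frac_{k}": v for k, v in fracs.items()},
                }
            )
            for name, seq in sorted(rrna_refs.items()):
                depth = rrna.density_profile(
                    [h for h in hits if h.subunit == name], name, len(seq)
                )
                dens_rows.append(
                    {
                        "sample": s.label,
                        "subunit": name,
                        "length": len(seq),
                        "mean_depth": float(depth.mean()) if len(depth) else 0.0,
                        "covered_bases": int((depth > 0).sum()),
                    }
                )
            logger.info(
                "%s: rRNA partition %d rRNA / %d remainder",
                s.label, len(assigned), len(remainder),
            )

            remainder_ids = {r.read_id for r in remainder}
            records = [
                r
                for r in alnfilter.load_alignments(aln_path)
                if r.read_id in remainder_ids
            ]
            kept, funnel = alnfilter.run_filters(
                records, config.min_aligned_len, config.min_mapq
            )
            rep = alnfilter.filter_funnel_report(funnel)
            rep.insert(0, "sample", s.label)
            funnel_rows.append(rep)
            logger.info("%s: filters kept %d/%d records", s.label, funnel.kept, funnel.input_records)

            comp = alnfilter.compartment_counts(kept, exon_index, len(assigned))
            comp.insert(0, "sample", s.label)
            comp_rows.append(comp)

            kept_blocks[s.label] = covdetect.blocks_by_reference(kept)

            # quantification (EM over compatible reads, RPKM over kept reads)
            matrix = quant.build_compatibility(kept, models, config.em_tolerance)
            if matrix.n_reads:
                ests = quant.em_abundance(
                    matrix, max_iter=config.em_max_iter
                )
                ests = quant.add_rpkm(ests, matrix, len(kept))
            else:
                ests = [
                    quant.AbundanceEstimate(tid, 0.0, 0.0, 0.0)
                    for tid in matrix.isoform_ids
                ]
            estimates[s.label] = ests

        # ---------------------------------------------------------- detection
        per_sample_cov: Dict[str, Dict[str, covdetect.CoverageResult]] = {}
        for label, by_ref in kept_blocks.items():
            per_sample_cov[label] = {
                m.transcript_id: covdetect.coverage_for_model(
                    by_ref.get(m.chrom, []), m
                )
                for m in models
            }
            df = covdetect.coverage_table(per_sample_cov[label].values())
            df.insert(0, "sample", label)
            cov_rows.append(df)

        if cell_label is not None:
            for m in models:
                calls.append(
                    covdetect.detect_cellular(
                        per_sample_cov[cell_label][m.transcript_id], cell_label
                    )
                )
        if exo_labels:
            pooled_blocks: Dict[str, List[Tuple[int, int]]] = {}
            for label in exo_labels:
                for chrom, blocks in kept_blocks[label].items():
                    pooled_blocks.setdefault(chrom, []).extend(blocks)
            for m in models:
                pooled = covdetect.coverage_for_model(
                    pooled_blocks.get(m.chrom, []), m
                )
                calls.extend(
                    covdetect.detect_exosomal(
                        pooled,
                        {
                            label: per_sample_cov[label][m.transcript_id]
                            for label in exo_labels
                        },
                    )
                )

        for label in [cell_label] * (cell_label is not None) + exo_labels:
            detected_genes[label] = covdetect.gene_level_detect(
                [c for c in calls if c.sample == label], models
            )

        class_table, nc_table = covdetect.biotype_summary(detected_genes)
        symbol_sets = {
            label: set(df["gene_name"]) for label, df in detected_genes.items()
        }
        overlaps = covdetect.overlap_sets(symbol_sets, cellular=cell_label)
        overlap_df = pd.DataFrame(
            [
                {"set_a": a, "set_b": b, "intersection": v}
                for (a, b), v in overlaps["pairwise"].items()
            ]
        )
        pct_df = pd.DataFrame(
            [
                {"sample": k, "pct_symbols_in_cellular": v}
                for k, v in overlaps["pct_in_cellular"].items()
            ]
        )

        # --------------------------------------------------------- enrichment
        enrichment = None
        if config.enrichment_table:
            ann = stats.read_annotation_table(config.enrichment_table)
            union_detected = set().union(
                *(set(df["gene_name"]) for df in detected_genes.values())
            ) if detected_genes else set()
            enrichment = stats.enrich_categories(
                union_detected & ann.universe,
                ann,
                min_count=config.enrichment_min_count,
                ease_cutoff=config.enrichment_ease,
                q_cutoff=config.enrichment_q,
            )

        # ------------------------------------------------------------ outputs
        tables["qc"] = pd.DataFrame(qc_rows)
        tables["rrna_partition"] = pd.DataFrame(part_rows)
        tables["rrna_density"] = pd.DataFrame(dens_rows)
        tables["filter_funnel"] = pd.concat(funnel_rows, ignore_index=True)
        tables["compartments"] = pd.concat(comp_rows, ignore_index=True)
        coverage_df = pd.concat(cov_rows, ignore_index=True)
        detection_df = covdetect.calls_table(calls)
        tables["detection"] = detection_df
        tables["coverage"] = coverage_df
        tables["abundance"] = quant.abundance_table(estimates, models)
        tables["class_split"] = class_table
        tables["noncoding_biotypes"] = nc_table
        tables["overlaps"] = overlap_df
        tables["overlap_pct"] = pct_df
        if enrichment is not None:
            tables["enrichment"] = enrichment

        stage_tables = {
            "qc": ["qc"],
            "rrna_partition": ["rrna_partition"],
            "rrna_density": ["rrna_density"],
            "filter_funnel": ["filter_funnel"],
            "compartments": ["compartments"],
            "detection": ["coverage", "detection"],
            "abundance": ["abundance"],
            "summary": ["class_split", "noncoding_biotypes", "overlaps", "overlap_pct"]
            + (["enrichment"] if enrichment is not None else []),
        }
        for stage, names in stage_tables.items():
            manifest["stages"][stage] = [
                os.path.basename(_write(tables[n], os.path.join(outdir, f"{n}.tsv")))
                for n in names
            ]
    except Exception as exc:  # partial outputs stay; manifest marks failure
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return ReportBundle(config, tables, manifest)


def write_report(bundle: ReportBundle, outdir: Optional[str] = None) -> str:
    """Consolidated report: one TSV per summary plus an index file."""
    outdir = outdir or bundle.config.output_dir
    os.makedirs(outdir, exist_ok=True)
    index_rows = []
    for name in (
        "class_split",
        "noncoding_biotypes",
        "overlaps",
        "overlap_pct",
        "compartments",
        "filter_funnel",
    ):
        if name in bundle.tables:
            path = _write(bundle.tables[name], os.path.join(outdir, f"report_{name}.tsv"))
            index_rows.append({"table": name, "file": os.path.basename(path)})
    index_path = os.path.join(outdir, "report_index.tsv")
    pd.DataFrame(index_rows).to_csv(index_path, sep="\t", index=False)
    return index_path
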
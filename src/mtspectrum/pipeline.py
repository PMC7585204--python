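"""End-to-end orchestration: config, staging, manifest.

``run_pipeline`` executes downsample -> extract -> post-filter ->
classify for every sample, then the repeat, breakpoint-identity,
spectrum, and cohort-statistics stages, writing tidy TSV/JSON outputs
and a manifest recording the configuration hash, seeds, and per-stage
record counts.  ``make_fixtures`` materializes a synthetic dataset
(genome, doubled-reference FASTA, per-sample SAM, metadata, truth
tables) from a YAML simulation config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circular, extract, identity, repeats, simulate, spectrum

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    snv_min_support: int = 4
    snv_min_depth: int = 50
    snv_min_quality: float = 20.0
    del_min_support: int = 2
    del_min_depth: int = 25
    del_min_quality: float = 10.0
    min_allele_fraction: float = 0.005
    trim_border: int = 5
    vlrd_boundary: int = 15000
    repeat_min_len: int = 8
    repeat_max_mismatch_rate: float = 0.25
    identity_flank: int = 10
    gap_open: float = 10.0
    gap_extend: float = 0.5
    sharing_bin: int = 10
    profile_bin: int = 100

    def __post_init__(self):
        for name, val in asdict(self).items():
            if isinstance(val, (int, float)) and val <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class RunConfig:
    reference_fasta: str
    sam_paths: list
    annotation_bed: str | None = None
    metadata_tsv: str | None = None
    output_dir: str = "mtspectrum_out"
    seed: int = 0
    downsample_to: int | None = None
    null_replicates: int = 1
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def digest(self) -> str:
        blob = json.dumps(
            {**{k: v for k, v in self.__dict__.items() if k != "thresholds"},
             "thresholds": asdict(self.thresholds)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample


def _preflight(cfg: RunConfig) -> None:
    missing = [p for p in [cfg.reference_fasta, *cfg.sam_paths] if
               not Path(p).exists()]
    if cfg.annotation_bed and not Path(cfg.annotation_bed).exists():
        missing.append(cfg.annotation_bed)
    if cfg.metadata_tsv and not Path(cfg.metadata_tsv).exists():
        missing.append(cfg.metadata_tsv)
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    _preflight(cfg)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = cfg.thresholds

    genome = circular.genome_from_fasta(cfg.reference_fasta)
    if cfg.annotation_bed:
        genes = circular.read_bed_genes(cfg.annotation_bed, genome.L)
        genome = circular.CircularGenome(genome.name, genome.sequence, genes)

    manifest = {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "genome": {"name": genome.name, "L": genome.L,
                   "n_genes": len(genome.genes)},
        "samples": {},
    }
    all_classified = []
    for sam in cfg.sam_paths:
        sample_id = Path(sam).stem
        counts = {}
        try:
            records = simulate.read_sam(sam)
            counts["records_in"] = len(records)
            if cfg.downsample_to is not None:
                records = extract.downsample_alignments(
                    records, cfg.downsample_to, cfg.seed, sample_id
                )
            counts["records_used"] = len(records)
            raw = extract.extract_variants(
                records, genome, trim_border=thr.trim_border,
                min_fraction=thr.min_allele_fraction,
            )
            counts["raw_variants"] = len(raw)
            kept = extract.apply_post_filters(
                raw,
                snv_min_support=thr.snv_min_support,
                snv_min_depth=thr.snv_min_depth,
                snv_min_quality=thr.snv_min_quality,
                del_min_support=thr.del_min_support,
                del_min_depth=thr.del_min_depth,
                del_min_quality=thr.del_min_quality,
            )
            counts["filtered_variants"] = len(kept)
            classified = extract.classify_deletions(
                kept, sample_id=sample_id, boundary=thr.vlrd_boundary
            )
            counts["discordant_reads"] = extract.count_discordant(records)
        except Exception as exc:  # noqa: BLE001 - rethrown with context
            raise PipelineError("extract", sample_id, exc) from exc
        all_classified.extend(classified)
        manifest["samples"][sample_id] = counts

    extract.write_variants_tsv(all_classified, out / "variants.tsv")
    extract.write_variants_vcf(all_classified, genome, out / "variants.vcf")

    # repeat analysis on pooled ordinary deletions
    catalogue = repeats.find_direct_repeats(
        genome, min_len=thr.repeat_min_len,
        max_mismatch_rate=thr.repeat_max_mismatch_rate,
    )
    repeats.write_repeats_tsv(catalogue, out / "direct_repeats.tsv")
    manifest["n_direct_repeats"] = len(catalogue)

    dels = [cv for cv in all_classified if cv.vclass == "DEL"]
    observed = [(cv.pos5, cv.length) for cv in dels]
    if observed and catalogue:
        comparisons = []
        for b in range(cfg.null_replicates):
            null = repeats.generate_null_library(
                observed, genome.L, cfg.seed + 7919 * b
            )
            if b == 0:
                repeats.write_null_library_tsv(null, genome.L,
                                               out / "null_library.tsv")
            comparisons.append(
                repeats.compare_observed_vs_null(observed, null, catalogue,
                                                 genome.L)
            )
        pooled = comparisons[0] if len(comparisons) == 1 else {
            "mean_obs": float(np.mean([c["mean_obs"] for c in comparisons])),
            "mean_null": float(np.mean([c["mean_null"] for c in comparisons])),
            "p": [c["p"] for c in comparisons],
            "replicates": len(comparisons),
        }
        (out / "repeat_comparison.json").write_text(
            json.dumps(pooled, indent=2, default=str)
        )
        manifest["repeat_comparison"] = {
            k: pooled[k] for k in ("mean_obs", "mean_null", "p")
        }

        ident = identity.breakpoint_window_identity(
            dels, genome, flank=thr.identity_flank
        )
        identity.write_identity_tsv(ident, out / "breakpoint_identity.tsv")
        identity.dump_alignments(ident, out / "breakpoint_alignments.txt")
        rel = identity.identity_length_relation(ident)
        manifest["identity_length_r"] = rel["r"]

    # spectrum summaries
    snvs = [cv for cv in all_classified if cv.vclass == "SNV"]
    if snvs:
        spec = spectrum.mutation_spectrum(
            [(cv.pos5, cv.ref, cv.alt) for cv in snvs], genome
        )
        (out / "mutation_spectrum.json").write_text(
            json.dumps({"counts": spec.counts, "Ti": spec.transitions,
                        "Tv": spec.transversions}, indent=2)
        )
        profile = spectrum.binned_allele_fraction(
            [(cv.pos5, cv.allele_fraction) for cv in snvs], genome.L,
            bin_width=thr.profile_bin,
        )
        pd.DataFrame({"bin": range(len(profile.values)),
                      "value": profile.values}).to_csv(
            out / "allele_fraction_profile.tsv", sep="\t", index=False
        )
        if genome.genes:
            load = spectrum.per_gene_load(all_classified, genome)
            pd.DataFrame({"gene": load["genes"], "snv_load": load["snv_load"],
                          "del_load": load["del_load"]}).to_csv(
                out / "per_gene_load.tsv", sep="\t", index=False
            )
            manifest["gene_load_r"] = load["r"]

    # cohort statistics
    if cfg.metadata_tsv:
        meta = pd.read_csv(cfg.metadata_tsv, sep="\t")
        per_sample = (
            extract.variants_to_frame(all_classified)
            .groupby(["sample_id", "class"]).size().unstack(fill_value=0)
            .reset_index()
        )
        table = meta.merge(per_sample, on="sample_id", how="left").fillna(0)
        table.to_csv(out / "cohort_counts.tsv", sep="\t", index=False)
        from .stats import anova_factorial

        stats_report = {}
        for col in ("SNV", "DEL"):
            if col in table.columns and table[col].nunique() > 1:
                factors = [f for f in ("age_weeks", "region", "animal")
                           if f in table.columns and table[f].nunique() > 1]
                if len(factors) >= 2:
                    res = anova_factorial(table, col, factors,
                                          tukey_factors=["age_weeks"])
                    stats_report[col] = res["p_values"]
        (out / "cohort_stats.json").write_text(
            json.dumps(stats_report, indent=2)
        )
        manifest["cohort_stats"] = stats_report

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    return manifest


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def make_fixtures(config_path, out_dir) -> dict:
    """Write a synthetic dataset from a YAML simulation description.

    The YAML mirrors ``SimulationConfig`` plus an optional ``cohort``
    block (``CohortDesign`` fields).  Returns a small summary dict.
    """
    raw = yaml.safe_load(Path(config_path).read_text()) or {}
    cohort_raw = raw.pop("cohort", None)
    plans = {
        "repeat_plan": simulate.RepeatPlan,
        "snv_plan": simulate.SnvPlan,
        "deletion_plan": simulate.DeletionPlan,
        "vlrd_plan": simulate.DeletionPlan,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in plans:
            kwargs[key] = tuple(plans[key](**item) for item in value)
        else:
            kwargs[key] = value
    cfg = simulate.SimulationConfig(**kwargs)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, planted = simulate.generate_genome(cfg)
    circular.write_fasta(out / "genome.fa", {genome.name: genome.sequence})
    circular.write_doubled_fasta(
        out / "genome_dMT.fa", circular.build_doubled_reference(genome)
    )
    circular.write_bed_genes(out / "genes.bed", genome)
    records, truth = simulate.simulate_alignments(genome, cfg)
    simulate.write_sam(out / "sample.sam", records, genome)
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)

    summary = {
        "genome": genome.name,
        "L": genome.L,
        "n_records": len(records),
        "n_planted": len(truth.variants),
        "planted_repeats": planted,
        "seed": cfg.seed,
    }
    if cohort_raw is not None:
        design = simulate.CohortDesign(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in cohort_raw.items()
        })
        table = simulate.simulate_cohort(design, seed=cfg.seed)
        table.to_csv(out / "cohort_counts.tsv", sep="\t", index=False)
        summary["n_cohort_samples"] = len(table)
    (out / "fixture_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
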
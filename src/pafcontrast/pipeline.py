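"""End-to-end orchestration: simulate-or-read, QC, estimate, compare,
stratify, enrich, report.

Two QC configurations drive the two analysis branches. The full-cohort
frequency comparison drops only strand-ambiguous SNPs (monomorphic and
low-frequency SNPs stay in, with boundary intervals); the admixture branch
applies the stricter call-rate / MAF / HWE thresholds before computing IBS
distances, since rare and badly called SNPs contribute noise, not ancestry
signal, to the embedding.

All outputs are TSV/JSON under the run's output directory, and identical
config + seed gives identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import genio
from .admixture_mds import stratify_cohort, stratified_comparison
from .cohort_comparison import (
    ComparisonConfig,
    absolute_difference_summary,
    calls_to_frame,
    compare_cohorts,
    summarize_differences,
    tabulate_by_bin,
)
from .group_enrichment import EnrichmentConfig, run_enrichment, results_to_frame
from .paf_estimation import estimate_cohort, estimates_to_frame
from .snp_qc import QcConfig, apply_qc
from .synthetic_data import SimConfig, generate_dataset, write_truth_table

log = logging.getLogger("pafcontrast")

#: strand filter only — the full-cohort comparison keeps monomorphic and
#: low-call SNPs, relying on the boundary CI convention
COMPARISON_QC = QcConfig(
    snp_call_rate_min=0.0, sample_call_rate_min=0.0, maf_min=0.0,
    hwe_p_min=0.0, drop_strand_ambiguous=True,
)


@dataclass
class InputPaths:
    genotypes: str
    snp_table: str
    reference: str
    groups: str


@dataclass
class RunConfig:
    """One pipeline run: either a simulation block or input paths."""

    sim: SimConfig | None = None
    inputs: InputPaths | None = None
    comparison_qc: QcConfig = field(default_factory=lambda: COMPARISON_QC)
    admixture_qc: QcConfig = field(default_factory=QcConfig)
    comparison: ComparisonConfig = field(default_factory=ComparisonConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    admixture: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of sim / inputs must be given")


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "sim" in raw:
        sim = dict(raw["sim"])
        if "freq_spectrum" in sim:
            from .synthetic_data import FreqSpectrum

            sim["freq_spectrum"] = FreqSpectrum(**sim["freq_spectrum"])
        if "divergence_magnitude" in sim:
            sim["divergence_magnitude"] = tuple(sim["divergence_magnitude"])
        if "enriched_groups" in sim:
            sim["enriched_groups"] = tuple(tuple(x) for x in sim["enriched_groups"])
        kwargs["sim"] = SimConfig(**sim)
    if "inputs" in raw:
        kwargs["inputs"] = InputPaths(**raw["inputs"])
    for name, cls in (
        ("comparison_qc", QcConfig),
        ("admixture_qc", QcConfig),
        ("comparison", ComparisonConfig),
        ("enrichment", EnrichmentConfig),
    ):
        if name in raw:
            kwargs[name] = cls(**raw[name])
    for name in ("admixture", "seed"):
        if name in raw:
            kwargs[name] = raw[name]
    return RunConfig(**kwargs)


def _load_inputs(config: RunConfig, outdir: Path):
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=config.seed)
        log.info("simulating dataset: %d SNPs, %d samples", sim.n_snps, sim.n_samples_study)
        genotypes, reference, records, mapping, truth = generate_dataset(sim)
        write_truth_table(truth, outdir / "truth.tsv")
        genio.write_snp_table(records, outdir / "snp_table.tsv")
        genio.write_reference_frequencies(reference, outdir / "reference_frequencies.tsv")
        genio.write_group_mapping(mapping, outdir / "group_mapping.tsv")
        return genotypes, reference, records, mapping
    paths = config.inputs
    records = genio.read_snp_table(paths.snp_table)
    genotypes = genio.read_genotype_table(paths.genotypes, records)
    reference = genio.read_reference_frequencies(paths.reference)
    mapping = genio.read_group_mapping(paths.groups)
    return genotypes, reference, records, mapping


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and write all artifacts; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genotypes, reference, records, mapping = _load_inputs(config, outdir)
    by_id = {r.snp_id: r for r in records}

    # -- comparison branch QC (strand filter by default)
    filtered, qc_report = apply_qc(genotypes, records, config.comparison_qc)
    qc_report.to_json(outdir / "qc_report_comparison.json")
    log.info(
        "comparison QC: %d/%d SNPs kept (%d strand-ambiguous removed)",
        len(qc_report.surviving_snps), qc_report.n_snps_in, qc_report.snps_strand_ambiguous,
    )

    # -- estimation and CI-overlap classification
    counted = {r.snp_id: r.counted_allele for r in records}
    estimates = estimate_cohort(filtered, counted, config.comparison.z_quantile)
    estimates_to_frame(estimates).to_csv(outdir / "study_estimates.tsv", sep="\t", index=False)
    calls = compare_cohorts(estimates, by_id, reference, config.comparison)
    calls_to_frame(calls).to_csv(outdir / "difference_calls.tsv", sep="\t", index=False)
    greater, less, either = summarize_differences(calls)
    bin_table = tabulate_by_bin(calls)
    bin_table.to_csv(outdir / "bin_table.tsv", sep="\t")
    abs_diff = absolute_difference_summary(calls, config.comparison)

    # -- functional-group enrichment
    group_results, meta = run_enrichment(calls, mapping, config.enrichment)
    results_to_frame(group_results).to_csv(outdir / "group_results.tsv", sep="\t", index=False)
    with open(outdir / "meta_result.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(meta), fh, indent=2, sort_keys=True)

    summary = {
        "n_snps_input": genotypes.n_snps,
        "n_samples": genotypes.n_samples,
        "n_snps_compared": sum(c.comparable for c in calls),
        "n_strand_ambiguous_removed": qc_report.snps_strand_ambiguous,
        "proportion_greater": greater,
        "proportion_less": less,
        "proportion_either": either,
        "absolute_difference": {f"ge_{t:g}pct": v for t, v in abs_diff.items()},
        "bin_table": json.loads(bin_table.to_json(orient="split")),
        "enrichment": {
            "n_groups": meta.n_groups,
            "n_significant": meta.n_significant,
            "bonferroni_threshold": meta.bonferroni_threshold,
            "meta_probability": meta.meta_probability,
            "n_more": meta.n_more,
            "n_less": meta.n_less,
            "sign_test_probability": meta.sign_test_probability,
        },
    }

    # -- admixture branch
    if config.admixture:
        strat_genotypes, strat_report = apply_qc(genotypes, records, config.admixture_qc)
        strat_report.to_json(outdir / "qc_report_admixture.json")
        result = stratify_cohort(strat_genotypes)
        result.to_frame().to_csv(outdir / "mds_coordinates.tsv", sep="\t")
        per_subgroup = stratified_comparison(
            result.labels, filtered, by_id, reference, config.comparison
        )
        result.per_subgroup = {k: v["summary"] for k, v in per_subgroup.items()}
        summary["stratified"] = {
            label: {
                "n_samples": result.labels.count(label),
                "proportion_greater": s[0],
                "proportion_less": s[1],
                "proportion_either": s[2],
            }
            for label, s in result.per_subgroup.items()
        }

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
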
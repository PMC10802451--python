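"""End-to-end orchestration: filter -> spectrum -> motif enrichment,
and the plate-assay comparison, with machine-readable reports.

A run is a pure function of its inputs and configuration: the manifest
written next to the outputs records the config, package version and
SHA-256 checksums of every input file, so identical inputs reproduce
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .assaystats import compare_groups, read_assay_table, write_comparisons
from .refgenome import MotifSpec, load_fasta
from .spectrum import build_spectrum
from .trims import cohort_enrichment, write_enrichment_results
from .variants import read_variants, run_filter_cascade, write_filter_reports

log = logging.getLogger("mutmotif")

__all__ = ["RunConfig", "run_genomics", "run_assay"]


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run (YAML key-value file;
    CLI flags override)."""

    genome: str | None = None
    variants: dict = field(default_factory=dict)   # sample -> path
    parent: str | None = None
    assay_table: str | None = None
    motif_pattern: str = "gCn"
    motif_alt: str = "A"
    flank: int = 20
    vaf_threshold: float = 0.90
    min_samples: int = 2
    mode: str = "per-sample"
    context_source: str = "windows"
    adjust: bool = False
    outdir: str = "mutmotif_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def motif(self) -> MotifSpec:
        return MotifSpec(self.motif_pattern, self.motif_alt)

    def validate_genomics(self) -> None:
        if self.genome is None or not Path(self.genome).exists():
            raise FileNotFoundError(f"genome FASTA not found: {self.genome}")
        if not self.variants:
            raise ValueError("no per-sample variant files configured")
        for sample, path in self.variants.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"variants for {sample!r} not found: {path}")
        if self.parent is not None and not Path(self.parent).exists():
            raise FileNotFoundError(f"parent variants not found: {self.parent}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(config: RunConfig, outdir: Path, inputs: list) -> None:
    manifest = {
        "tool": "mutmotif",
        "version": __version__,
        "config": asdict(config),
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_genomics(config: RunConfig) -> dict:
    """Filter cascade, spectrum and motif enrichment for one cohort.

    Writes filter_report, spectrum, enrichment tables and a manifest to
    the output directory; returns the in-memory results.
    """
    config.validate_genomics()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = load_fasta(config.genome)
    log.info("loaded genome: %d contig(s), %d bp",
             len(genome.contigs), genome.total_length)

    calls_by_sample = {s: read_variants(p, sample=s)
                       for s, p in sorted(config.variants.items())}
    parent_calls = (read_variants(config.parent, sample="parent")
                    if config.parent else [])
    for s, calls in calls_by_sample.items():
        log.info("sample %s: %d input calls", s, len(calls))

    kept, reports = run_filter_cascade(
        calls_by_sample, parent_calls,
        vaf_threshold=config.vaf_threshold, min_samples=config.min_samples)
    for s, r in reports.items():
        log.info("sample %s: kept %d / %d (non-SNV %d, VAF %d, parent %d, "
                 "recurrent %d)", s, r.n_kept, r.n_input, r.n_removed_non_snv,
                 r.n_removed_vaf, r.n_removed_parent, r.n_removed_recurrent)
    write_filter_reports(reports, outdir / "filter_report.tsv",
                         outdir / "filter_report.json")

    spectrum = build_spectrum(kept, genome, contexts=True)
    spectrum.write(outdir / "spectrum_long.tsv", outdir / "spectrum_summary.tsv")

    results = cohort_enrichment(
        kept, genome, motif=config.motif(), flank=config.flank,
        mode=config.mode, adjust=config.adjust,
        context_source=config.context_source)
    write_enrichment_results(results, outdir / "enrichment.tsv",
                             outdir / "enrichment.json")

    inputs = [config.genome, *config.variants.values()]
    if config.parent:
        inputs.append(config.parent)
    _write_manifest(config, outdir, inputs)
    return {"filter_reports": reports, "spectrum": spectrum,
            "enrichment": results, "kept": kept}


def run_assay(config: RunConfig) -> dict:
    """Per-genotype treated-vs-untreated comparison from an assay table.

    Treatment labels: any group labelled ``water`` (or ``untreated``)
    is the reference; every other treatment in the same genotype is
    compared against it.
    """
    if config.assay_table is None or not Path(config.assay_table).exists():
        raise FileNotFoundError(f"assay table not found: {config.assay_table}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    measurements = read_assay_table(config.assay_table)
    by_group: dict = {}
    for m in measurements:
        by_group.setdefault((m.genotype, m.treatment), []).append(m)

    comparisons = []
    genotypes = sorted({g for g, _ in by_group})
    for genotype in genotypes:
        treatments = [t for g, t in by_group if g == genotype]
        ref = next((t for t in treatments
                    if t.lower() in ("water", "untreated", "none")), None)
        if ref is None:
            log.warning("genotype %s: no untreated reference group; skipped",
                        genotype)
            continue
        for t in treatments:
            if t == ref:
                continue
            comp = compare_groups(by_group[(genotype, ref)],
                                  by_group[(genotype, t)])
            log.info("%s %s vs %s: fold %.3g, one-sided p %.3g", genotype, t,
                     ref, comp.fold_change or float("nan"), comp.p)
            comparisons.append(comp)

    write_comparisons(comparisons, outdir / "assay_comparisons.tsv",
                      outdir / "assay_comparisons.json")
    _write_manifest(config, outdir, [config.assay_table])
    return {"measurements": measurements, "comparisons": comparisons}
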
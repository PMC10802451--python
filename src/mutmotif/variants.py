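"""Variant ingestion and the isolate-filtering cascade.

Sequenced Can^R isolates yield per-sample variant calls.  Before any
spectrum or enrichment statistic, calls pass a fixed filtering cascade:

1. non-SNV removal (indels/MNVs are set aside — downstream statistics
   are defined on single-base substitutions),
2. variant-allele-frequency (VAF) filter — clonal haploid mutations are
   expected near 100% VAF, so sub-threshold calls are artifacts or
   subclonal events (default threshold 0.90, kept iff vaf >= threshold),
3. parent-strain subtraction — calls also present in the untreated
   parent culture are pre-existing,
4. recurrence removal — a variant key (contig, pos, ref, alt) seen in
   two or more isolates is pre-existing in the shared culture and is
   removed from every isolate carrying it.

Each removed call is attributed to exactly one stage, in that order, so
the per-sample FilterReport counters always balance.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

__all__ = [
    "VariantCall",
    "FilterReport",
    "read_variants",
    "write_variants_tsv",
    "filter_vaf",
    "subtract_parent",
    "remove_recurrent",
    "run_filter_cascade",
    "write_filter_reports",
]

_TSV_COLUMNS = ["sample", "contig", "pos", "ref", "alt", "vaf"]


class VariantParseError(ValueError):
    pass


@dataclass(frozen=True)
class VariantCall:
    """One substitution call from one isolate."""

    contig: str
    pos: int          # 1-based
    ref: str
    alt: str
    vaf: float        # variant allele frequency in [0, 1]
    sample: str = ""

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.contig}:{self.pos}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1] at {self.contig}:{self.pos}")

    @property
    def key(self) -> tuple:
        """Identity used for parent subtraction and recurrence matching."""
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return (len(self.ref) == 1 and len(self.alt) == 1
                and self.ref in "ACGT" and self.alt in "ACGT")


@dataclass
class FilterReport:
    """Per-sample accounting of the filter cascade."""

    sample: str
    n_input: int = 0
    n_kept: int = 0
    n_removed_non_snv: int = 0
    n_removed_vaf: int = 0
    n_removed_parent: int = 0
    n_removed_recurrent: int = 0

    def balances(self) -> bool:
        return self.n_input == (self.n_kept + self.n_removed_non_snv
                                + self.n_removed_vaf + self.n_removed_parent
                                + self.n_removed_recurrent)


def _vaf_from_vcf_record(variant, allele_index: int, default_vaf):
    """VAF for one alternate allele: FORMAT FREQ (VarScan percent
    string), then FORMAT AF, then INFO AF, then the configured default."""
    try:
        freq = variant.format("FREQ")
    except KeyError:
        freq = None
    if freq is not None:
        raw = freq[0]
        if isinstance(raw, bytes):
            raw = raw.decode()
        if not isinstance(raw, str):
            raw = str(raw)
        raw = raw.split(",")[min(allele_index, len(raw.split(",")) - 1)]
        return float(raw.rstrip("%")) / 100.0 if raw.endswith("%") else float(raw)
    try:
        af = variant.format("AF")
    except KeyError:
        af = None
    if af is not None:
        row = af[0]
        try:
            return float(row[min(allele_index, len(row) - 1)])
        except TypeError:
            return float(row)
    info_af = variant.INFO.get("AF")
    if info_af is not None:
        if isinstance(info_af, tuple):
            return float(info_af[min(allele_index, len(info_af) - 1)])
        return float(info_af)
    if default_vaf is not None:
        return float(default_vaf)
    raise VariantParseError(
        f"no VAF field (FORMAT FREQ/AF or INFO AF) at "
        f"{variant.CHROM}:{variant.POS} and no default configured")


def _read_vcf(path: str, sample: str, default_vaf) -> list[VariantCall]:
    from cyvcf2 import VCF

    calls = []
    for variant in VCF(path):
        for i, alt in enumerate(variant.ALT):
            calls.append(VariantCall(
                contig=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=alt,
                vaf=_vaf_from_vcf_record(variant, i, default_vaf),
                sample=sample,
            ))
    return calls


def _read_tsv(path: str, sample: str, default_vaf) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _TSV_COLUMNS if c not in df.columns and c != "vaf"]
    if missing:
        raise VariantParseError(f"{path}: missing column(s) {missing}")
    calls = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            if "vaf" in df.columns and not pd.isna(row.vaf):
                vaf = float(row.vaf)
            elif default_vaf is not None:
                vaf = float(default_vaf)
            else:
                raise ValueError("missing VAF and no default configured")
            for alt in str(row.alt).split(","):
                calls.append(VariantCall(
                    contig=str(row.contig), pos=int(row.pos),
                    ref=str(row.ref), alt=alt, vaf=vaf,
                    sample=sample if sample is not None else str(row.sample),
                ))
        except (TypeError, ValueError) as exc:
            raise VariantParseError(f"{path}: line {line_no}: {exc}") from exc
    return calls


def read_variants(path, sample: str | None = None,
                  default_vaf: float | None = None) -> list[VariantCall]:
    """Read one isolate's calls from a VCF (``*.vcf``/``*.vcf.gz``) or
    the tab-separated dialect (columns sample, contig, pos, ref, alt,
    vaf).  Multi-allelic records are split into one call per alternate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".vcf" or path.suffixes[-2:] == [".vcf", ".gz"]:
        return _read_vcf(str(path), sample or path.stem, default_vaf)
    return _read_tsv(str(path), sample, default_vaf)


def write_variants_tsv(calls: list[VariantCall], path) -> None:
    df = pd.DataFrame(
        [(c.sample, c.contig, c.pos, c.ref, c.alt, c.vaf) for c in calls],
        columns=_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def filter_vaf(calls, threshold: float = 0.90):
    """Partition calls into (kept, removed) by vaf >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"VAF threshold {threshold} outside [0, 1]")
    kept = [c for c in calls if c.vaf >= threshold]
    removed = [c for c in calls if c.vaf < threshold]
    return kept, removed


def subtract_parent(calls, parent_calls):
    """Remove calls whose (contig, pos, ref, alt) matches a parent call."""
    parent_keys = {c.key for c in parent_calls}
    kept = [c for c in calls if c.key not in parent_keys]
    removed = [c for c in calls if c.key in parent_keys]
    return kept, removed


def remove_recurrent(calls_by_sample: dict, min_samples: int = 2):
    """Remove variant keys observed in >= min_samples distinct samples
    from every sample carrying them."""
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    sample_count: Counter = Counter()
    for sample, calls in calls_by_sample.items():
        for key in {c.key for c in calls}:
            sample_count[key] += 1
    recurrent = {k for k, n in sample_count.items() if n >= min_samples}
    kept_by_sample = {}
    removed_by_sample = {}
    for sample, calls in calls_by_sample.items():
        kept_by_sample[sample] = [c for c in calls if c.key not in recurrent]
        removed_by_sample[sample] = [c for c in calls if c.key in recurrent]
    return kept_by_sample, removed_by_sample


def run_filter_cascade(calls_by_sample: dict, parent_calls=(),
                       vaf_threshold: float = 0.90, min_samples: int = 2):
    """Apply the full cascade (SNV-only -> VAF -> parent -> recurrent).

    Returns ``(kept_by_sample, reports_by_sample)`` where every input
    call lands in exactly one bucket of its sample's FilterReport.
    """
    reports = {s: FilterReport(sample=s, n_input=len(calls))
               for s, calls in calls_by_sample.items()}

    stage: dict[str, list[VariantCall]] = {}
    for sample, calls in calls_by_sample.items():
        snvs = [c for c in calls if c.is_snv]
        reports[sample].n_removed_non_snv = len(calls) - len(snvs)
        kept, removed = filter_vaf(snvs, vaf_threshold)
        reports[sample].n_removed_vaf = len(removed)
        kept, removed = subtract_parent(kept, parent_calls)
        reports[sample].n_removed_parent = len(removed)
        stage[sample] = kept

    kept_by_sample, removed_by_sample = remove_recurrent(stage, min_samples)
    for sample in calls_by_sample:
        reports[sample].n_removed_recurrent = len(removed_by_sample[sample])
        reports[sample].n_kept = len(kept_by_sample[sample])
        assert reports[sample].balances()
    return kept_by_sample, reports


def write_filter_reports(reports: dict, tsv_path=None, json_path=None) -> None:
    rows = [asdict(r) for r in reports.values()]
    if tsv_path is not None:
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2) + "\n")
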
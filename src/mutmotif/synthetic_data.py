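"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a random
reference genome with controllable GC content, cohorts of isolate
variant sets carrying a chosen true motif enrichment plus planted
filter confounders (shared pre-existing mutations, parent-strain
mutations, low-VAF artifacts), and plate-assay measurements with chosen
true mutation frequencies.  All generators are deterministic given a
seed, and every emitted call is categorized in a truth record so filter
accuracy and parameter recovery can be checked exactly.

Planting a motif enrichment
---------------------------
Class mutations (e.g. C>A on either strand) are placed by weighted
sampling over the genome's class sites, with motif sites up-weighted
relative to non-motif sites.  The weight is *calibrated* so that the
expectation of the enrichment statistic

    E = (m_motif / m_class) / (x_motif / x_class)

equals the requested E*.  The expected numerator fraction is the motif
fraction r among mutations; the expected denominator is a mixture of
the mean masked-window opportunity counts of motif-centered and
non-motif-centered sites, measured directly on the generated genome.
Setting expectation(E) = E* gives a quadratic in r:

    (xc_m - xc_n) r^2 + (xc_n - E*(xm_m - xm_n)) r - E* xm_n = 0

where (xm_m, xc_m) and (xm_n, xc_n) are the mean (motif, class)
opportunity counts of windows centered on motif and non-motif class
sites.  The motif-site weight follows from the site inventory as
w = r (1 - f) / (f (1 - r)) with f the genomic motif-site fraction.
An E* with no root in (0, 1) exceeds what the windowed statistic can
express on this genome and raises an error.  Since the motif fraction
among mutations can never exceed 1, arbitrarily large E* are
unattainable by any placement of mutations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .assaystats import AssayMeasurement
from .refgenome import GCN_TO_A, MotifSpec, ReferenceGenome, _IUPAC
from .variants import VariantCall

__all__ = [
    "CohortSpec",
    "generate_genome",
    "motif_site_positions",
    "class_site_positions",
    "generate_cohort",
    "generate_assay_data",
    "write_fasta",
    "write_vcf",
    "write_truth",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def generate_genome(length: int, gc_fraction: float = 0.38,
                    seed: int | None = None, contig: str = "chr1"
                    ) -> ReferenceGenome:
    """Random genome with i.i.d. bases: P(G) = P(C) = gc/2."""
    if length < 100:
        raise ValueError("genome length must be >= 100")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length,
                       p=[p_at, p_gc, p_gc, p_at])
    return ReferenceGenome({contig: "".join(bases)})


def _base_mask(arr: np.ndarray, code: str) -> np.ndarray:
    """Boolean mask of positions whose base satisfies an IUPAC code.
    'N' genome bases satisfy nothing."""
    allowed = _IUPAC[code.upper()]
    mask = np.zeros(arr.shape, dtype=bool)
    for b in allowed:
        mask |= arr == b
    return mask


def _pattern_mask(arr: np.ndarray, pattern: str, center: int) -> np.ndarray:
    """Positions p where pattern matches with its ``center`` index at p."""
    n = arr.size
    mask = np.ones(n, dtype=bool)
    for j, code in enumerate(pattern):
        shift = j - center
        shifted = np.zeros(n, dtype=bool)
        src = _base_mask(arr, code)
        if shift == 0:
            shifted = src
        elif shift > 0:
            shifted[:n - shift] = src[shift:]
        else:
            shifted[-shift:] = src[:n + shift]
        mask &= shifted
    return mask


def class_site_positions(genome: ReferenceGenome, motif: MotifSpec
                         ) -> list[tuple[str, int]]:
    """All (contig, 1-based pos) where the reference base belongs to the
    motif's mutated-base class on either strand (C or G for a
    C-centered motif)."""
    out = []
    for contig, seq in genome.contigs.items():
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        mask = (arr == motif.from_base) | (arr == _COMPLEMENT[motif.from_base])
        out.extend((contig, int(p) + 1) for p in np.flatnonzero(mask))
    return out


def motif_site_positions(genome: ReferenceGenome, motif: MotifSpec
                         ) -> list[tuple[str, int]]:
    """All (contig, 1-based pos) of strand-aware motif sites: the class
    base with the motif context read on its strand."""
    out = []
    c = motif.center_index
    rc_c = len(motif.pattern) - 1 - c
    for contig, seq in genome.contigs.items():
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        fwd = _pattern_mask(arr, motif.pattern, c)
        rev = _pattern_mask(arr, motif.rc_pattern, rc_c)
        out.extend((contig, int(p) + 1) for p in np.flatnonzero(fwd | rev))
    return out


@dataclass
class CohortSpec:
    """Conditions for a simulated isolate cohort.

    Defaults mirror a plate-assay sequencing experiment: 36 isolates
    per group, clonal VAFs near 1, a handful of shared pre-existing and
    parent-strain mutations, and a few sub-threshold artifacts per
    isolate.
    """

    genome_length: int = 100_000
    gc_fraction: float = 0.38
    n_samples: int = 36
    n_class_mutations: float = 200.0   # Poisson mean per sample
    true_enrichment: float = 1.0
    motif: MotifSpec = field(default_factory=lambda: GCN_TO_A)
    n_shared: int = 5
    n_parent: int = 3
    n_low_vaf: int = 4                 # per sample
    vaf_true: tuple[float, float] = (0.93, 1.0)
    vaf_artifact: tuple[float, float] = (0.10, 0.85)
    flank: int = 20                    # opportunity-window half-width (bp)
    distinct_sites: bool = True        # genuine sites unique across samples
    seed: int = 0

    def __post_init__(self):
        if self.true_enrichment < 0:
            raise ValueError("true_enrichment must be >= 0")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        for name in ("n_samples", "n_shared", "n_parent", "n_low_vaf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _window_stats(genome, motif: MotifSpec, sites, flags, flank: int,
                  rng: np.random.Generator, max_per_group: int = 1500):
    """Mean masked-window (x_motif, x_class) for motif-centered and
    non-motif-centered class sites, estimated from a site subsample."""
    from .refgenome import count_contexts
    from .trims import opportunity_window

    means = {}
    for label, want in (("motif", True), ("nonmotif", False)):
        idx = np.flatnonzero(flags == want)
        if idx.size > max_per_group:
            idx = rng.choice(idx, size=max_per_group, replace=False)
        windows = [opportunity_window(genome, sites[i][0], sites[i][1], flank)
                   for i in idx]
        xm, xc = count_contexts(windows, motif)
        means[label] = (xm / len(windows), xc / len(windows))
    return means


def _calibrated_motif_fraction(true_enrichment: float, stats: dict) -> float:
    """Motif fraction r among mutations such that the expected windowed
    enrichment estimate equals ``true_enrichment`` (quadratic root, see
    module docstring)."""
    xm_m, xc_m = stats["motif"]
    xm_n, xc_n = stats["nonmotif"]
    e = true_enrichment
    a = xc_m - xc_n
    b = xc_n - e * (xm_m - xm_n)
    c = -e * xm_n
    if abs(a) < 1e-12:
        roots = [-c / b] if b else []
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            roots = []
        else:
            roots = [(-b + np.sqrt(disc)) / (2 * a),
                     (-b - np.sqrt(disc)) / (2 * a)]
    valid = [r for r in roots if 0.0 < r < 1.0]
    if not valid:
        ceiling = xc_m / xm_m if xm_m > 0 else float("inf")
        raise ValueError(
            f"enrichment {true_enrichment} unattainable on this genome: "
            f"the windowed statistic saturates near {ceiling:.2f}")
    return float(min(valid))


def _weighted_sample(rng: np.random.Generator, weights: np.ndarray, k: int
                     ) -> np.ndarray:
    """k indices drawn without replacement with probability proportional
    to weight (Gumbel top-k; zero-weight entries are never drawn)."""
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=weights.size)
    if k >= np.count_nonzero(weights > 0):
        return np.flatnonzero(weights > 0)
    idx = np.argpartition(-keys, k)[:k]
    return idx


def _call_for_site(genome, motif, contig, pos, vaf, sample) -> VariantCall:
    ref = genome.base(contig, pos)
    alt = motif.to_base if ref == motif.from_base else _COMPLEMENT[motif.to_base]
    return VariantCall(contig=contig, pos=pos, ref=ref, alt=alt,
                       vaf=vaf, sample=sample)


def generate_cohort(spec: CohortSpec, genome: ReferenceGenome | None = None):
    """Simulate a cohort of isolate variant sets.

    Returns ``(calls_by_sample, parent_calls, truth)``.  The truth
    record categorizes every emitted call as genuine / shared / parent /
    low_vaf (the categories partition the calls), and records the
    motif-site fraction and sampling weight behind the planted
    enrichment.
    """
    rng = np.random.default_rng(spec.seed)
    if genome is None:
        genome = generate_genome(spec.genome_length, spec.gc_fraction,
                                 seed=rng.integers(2 ** 31))

    sites = class_site_positions(genome, spec.motif)
    motif_sites = set(motif_site_positions(genome, spec.motif))
    if not motif_sites or len(motif_sites) == len(sites):
        raise ValueError("genome must contain both motif and non-motif class sites")
    is_motif = np.array([s in motif_sites for s in sites])
    f = is_motif.mean()
    if spec.true_enrichment == 0.0:
        r = 0.0
        w = 0.0
    else:
        stats = _window_stats(genome, spec.motif, sites, is_motif,
                              spec.flank, rng)
        r = _calibrated_motif_fraction(spec.true_enrichment, stats)
        w = r * (1.0 - f) / (f * (1.0 - r))

    n_reserved = spec.n_shared + spec.n_parent + spec.n_low_vaf * spec.n_samples
    if n_reserved >= len(sites):
        raise ValueError("not enough class sites for the requested confounders")
    reserved_idx = rng.choice(len(sites), size=n_reserved, replace=False)
    shared_idx = reserved_idx[:spec.n_shared]
    parent_idx = reserved_idx[spec.n_shared:spec.n_shared + spec.n_parent]
    low_vaf_idx = reserved_idx[spec.n_shared + spec.n_parent:]

    weights = np.where(is_motif, w, 1.0)
    weights[reserved_idx] = 0.0        # confounder sites never carry genuine calls

    sample_names = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    calls_by_sample: dict[str, list[VariantCall]] = {s: [] for s in sample_names}
    truth = {
        "genuine": {s: [] for s in sample_names},
        "shared": [], "parent": [],
        "low_vaf": {s: [] for s in sample_names},
        "true_enrichment": spec.true_enrichment,
        "motif_fraction": float(f),
        "expected_motif_mutation_fraction": float(r),
        "motif_site_weight": float(w),
        "n_class_sites": len(sites),
    }

    def record(cat_list, call):
        cat_list.append({"contig": call.contig, "pos": call.pos,
                         "ref": call.ref, "alt": call.alt,
                         "vaf": call.vaf, "sample": call.sample})

    # genuine, enrichment-carrying mutations
    vlo, vhi = spec.vaf_true
    for s in sample_names:
        n = int(rng.poisson(spec.n_class_mutations))
        n = min(n, int(np.count_nonzero(weights > 0)))
        idx = _weighted_sample(rng, weights, n)
        if spec.distinct_sites:
            weights[idx] = 0.0
        for i in idx:
            contig, pos = sites[i]
            call = _call_for_site(genome, spec.motif, contig, pos,
                                  float(rng.uniform(vlo, vhi)), s)
            calls_by_sample[s].append(call)
            record(truth["genuine"][s], call)

    # shared pre-existing mutations: each duplicated into two samples
    for i in shared_idx:
        contig, pos = sites[i]
        carriers = rng.choice(spec.n_samples, size=min(2, spec.n_samples),
                              replace=False)
        for ci in carriers:
            s = sample_names[ci]
            call = _call_for_site(genome, spec.motif, contig, pos,
                                  float(rng.uniform(vlo, vhi)), s)
            calls_by_sample[s].append(call)
            record(truth["shared"], call)

    # parent-strain mutations: in the parent call set and one isolate
    parent_calls: list[VariantCall] = []
    for i in parent_idx:
        contig, pos = sites[i]
        parent_calls.append(_call_for_site(genome, spec.motif, contig, pos,
                                           1.0, "parent"))
        s = sample_names[int(rng.integers(spec.n_samples))]
        call = _call_for_site(genome, spec.motif, contig, pos,
                              float(rng.uniform(vlo, vhi)), s)
        calls_by_sample[s].append(call)
        record(truth["parent"], call)

    # sub-threshold-VAF artifacts
    alo, ahi = spec.vaf_artifact
    for j, s in enumerate(sample_names):
        for i in low_vaf_idx[j * spec.n_low_vaf:(j + 1) * spec.n_low_vaf]:
            contig, pos = sites[i]
            call = _call_for_site(genome, spec.motif, contig, pos,
                                  float(rng.uniform(alo, ahi)), s)
            calls_by_sample[s].append(call)
            record(truth["low_vaf"][s], call)

    for s in sample_names:
        calls_by_sample[s].sort(key=lambda c: (c.contig, c.pos, c.alt))
    return calls_by_sample, parent_calls, truth


def generate_assay_data(genotypes, true_freqs: dict, n_cultures: int = 12,
                        nominal_titer: float = 2e7, cells_plated: float = 2e7,
                        dispersion: float = 0.3,
                        true_viability: dict | None = None,
                        seed: int | None = None) -> list[AssayMeasurement]:
    """Simulate per-culture plate-assay measurements.

    ``true_freqs`` maps (genotype, treatment) to the true mutation
    frequency.  Per culture, the viable titer is log-normal around
    ``nominal_titer`` (scaled by ``true_viability[(genotype,
    treatment)]`` when given) with log-scale sigma ``dispersion``; the
    Can^R colony count is Poisson with mean frequency x viable cells in
    the plated volume, then converted back to a per-ml titer.
    """
    if n_cultures < 1 or nominal_titer <= 0 or cells_plated <= 0:
        raise ValueError("n_cultures, nominal_titer, cells_plated must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    volume_plated = cells_plated / nominal_titer     # ml
    out = []
    for genotype in genotypes:
        for (g, treatment), freq in true_freqs.items():
            if g != genotype:
                continue
            if freq < 0:
                raise ValueError(f"negative frequency for {(g, treatment)}")
            scale = 1.0
            if true_viability is not None:
                scale = true_viability.get((g, treatment), 1.0)
            for i in range(n_cultures):
                viable = (nominal_titer * scale
                          * float(np.exp(rng.normal(0.0, dispersion))))
                mean_colonies = freq * viable * volume_plated
                canr = int(rng.poisson(mean_colonies))
                out.append(AssayMeasurement(
                    culture=f"{g}-{treatment}-{i + 1}",
                    genotype=g, treatment=treatment,
                    canr_per_ml=canr / volume_plated,
                    viable_per_ml=viable))
    return out


# ---------------------------------------------------------------------------
# writers

def write_fasta(genome: ReferenceGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_vcf(calls, genome: ReferenceGenome, path, sample: str) -> None:
    """Minimal single-sample VCF (v4.2) with the VAF in FORMAT/AF."""
    lines = ["##fileformat=VCFv4.2"]
    for name, seq in genome.contigs.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AF,Number=1,Type=Float,'
                 'Description="Variant allele frequency">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + sample)
    for c in sorted(calls, key=lambda c: (c.contig, c.pos, c.alt)):
        lines.append(f"{c.contig}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t.\t"
                     f"GT:AF\t1:{c.vaf:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2) + "\n")
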
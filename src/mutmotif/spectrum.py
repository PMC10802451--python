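"""Pyrimidine-centered mutation spectra.

Every single-base substitution is folded onto the strand where the
reference base is a pyrimidine (C or T), giving six substitution
classes: C>A, C>G, C>T, T>A, T>C, T>G.  A G>T call is therefore counted
as C>A together with its complementary change.  Optionally each class
is subdivided by the reference trinucleotide context around the mutated
base (16 contexts x 6 classes = 96 channels, the convention used for
mutational-signature catalogues).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .refgenome import ReferenceGenome, reverse_complement
from .variants import VariantCall

__all__ = [
    "SUBSTITUTION_CLASSES",
    "SpectrumTable",
    "classify_substitution",
    "trinucleotide_context",
    "build_spectrum",
    "plot_spectrum",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_substitution(ref: str, alt: str) -> str:
    """Six-class pyrimidine-centered label for a single-base change."""
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"bases must be A,C,G,T; got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref})")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def trinucleotide_context(genome: ReferenceGenome, call: VariantCall) -> str:
    """Reference 3-mer centered on the call, folded so the center is a
    pyrimidine.  Positions beyond contig ends are padded with N."""
    if not call.is_snv:
        raise ValueError(f"not an SNV: {call.ref}>{call.alt}")
    seq = genome.sequence(call.contig)
    if not 1 <= call.pos <= len(seq):
        raise IndexError(f"position {call.pos} outside contig {call.contig!r}")
    i = call.pos - 1
    left = seq[i - 1] if i >= 1 else "N"
    right = seq[i + 1] if i + 1 < len(seq) else "N"
    context = left + seq[i] + right
    if seq[i] in "AG":
        context = reverse_complement(context)
    return context


@dataclass
class SpectrumTable:
    """Per-sample substitution-class counts plus cohort summaries.

    ``counts`` is samples x 6 classes; ``context_counts`` (optional) is
    samples x 96 channels labelled like ``A[C>A]G``, with N-containing
    contexts excluded.
    """

    counts: pd.DataFrame
    context_counts: pd.DataFrame | None = None

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def mean_per_isolate(self) -> pd.Series:
        """Arithmetic mean count per isolate for each class."""
        return self.counts.mean(axis=0)

    def write(self, long_tsv=None, summary_tsv=None) -> None:
        if long_tsv is not None:
            long = (self.counts.reset_index(names="sample")
                    .melt(id_vars="sample", var_name="class", value_name="count"))
            long.to_csv(long_tsv, sep="\t", index=False)
        if summary_tsv is not None:
            pd.DataFrame({"mean_per_isolate": self.mean_per_isolate,
                          "total": self.totals}).rename_axis("class") \
                .to_csv(summary_tsv, sep="\t")


def build_spectrum(calls_by_sample: dict, genome: ReferenceGenome | None = None,
                   contexts: bool = False) -> SpectrumTable:
    """Tabulate per-sample six-class spectra (and, with a genome and
    ``contexts=True``, the 96-channel table)."""
    samples = list(calls_by_sample)
    counts = pd.DataFrame(0, index=pd.Index(samples, name="sample"),
                          columns=list(SUBSTITUTION_CLASSES))
    ctx_counts = None
    if contexts:
        if genome is None:
            raise ValueError("a reference genome is required for context counts")
        channels = [f"{l}[{cls}]{r}"
                    for cls in SUBSTITUTION_CLASSES
                    for l in "ACGT" for r in "ACGT"]
        ctx_counts = pd.DataFrame(0, index=pd.Index(samples, name="sample"),
                                  columns=channels)
    for sample, calls in calls_by_sample.items():
        for call in calls:
            if not call.is_snv:
                raise ValueError(
                    f"non-SNV call {call.ref}>{call.alt} in sample {sample!r}; "
                    "run the filter cascade first")
            cls = classify_substitution(call.ref, call.alt)
            counts.loc[sample, cls] += 1
            if ctx_counts is not None:
                ctx = trinucleotide_context(genome, call)
                if "N" not in ctx:
                    ctx_counts.loc[sample, f"{ctx[0]}[{cls}]{ctx[2]}"] += 1
    return SpectrumTable(counts=counts, context_counts=ctx_counts)


def plot_spectrum(table: SpectrumTable, ax=None, per_isolate: bool = True):
    """Bar chart of the cohort spectrum (mean per isolate by default)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    values = table.mean_per_isolate if per_isolate else table.totals
    ax.bar(values.index, values.values, color="#555555")
    ax.set_ylabel("mutations per isolate" if per_isolate else "total mutations")
    ax.set_xlabel("substitution class (pyrimidine-centered)")
    return ax
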
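"""Trinucleotide-motif enrichment: fold-enrichment, one-sided Fisher
test, and motif-attributable mutation load.

For a motif such as gCn -> A the statistic asks whether, among a
sample's C>A mutations (counted on both strands), those falling in the
motif context are over-represented relative to the sequence opportunity
around the mutated sites.  With

* ``m_motif``  — class mutations whose strand-aware context matches the
  motif (a mutated C with a 5' g, or a mutated G with a 3' c),
* ``m_class``  — all mutations of the class (C>A plus G>T),
* ``x_motif``, ``x_class`` — double-stranded motif and class-base
  occurrence counts inside +/-flank windows around each class mutation,
  with the mutated position itself masked out (see below),

the fold-enrichment is

    E = (m_motif / m_class) / (x_motif / x_class)

E = 1 under the null that mutations fall proportionally to opportunity.
Enrichment is tested with a one-sided Fisher's exact test on the 2x2
table [[m_motif, m_class - m_motif], [x_motif, x_class - x_motif]]
(alternative: motif over-represented among mutations), and the number
of motif mutations attributable to the signature is

    load = m_motif * (E - 1) / E        (floored at 0 when E <= 1).

Why the mutated base is masked in the opportunity windows: every window
is centered on a mutation, so with the center included each window is
guaranteed to contain that mutation's own context.  The denominator
then rises with the numerator, and the estimate saturates — for window
length L the largest reportable enrichment is max_q qL/(q^2 L + 1),
about 3.2-3.6 for the default +/-20 bp windows, no matter how strong
the underlying bias.  Replacing the mutated position with N (which
matches neither the motif nor the base class) keeps the opportunity
set a property of the neighborhood rather than of the mutation, and
removes the ceiling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import pandas as pd
from scipy.stats import hypergeom

from .refgenome import (GCN_TO_A, MotifSpec, ReferenceGenome, count_contexts,
                        window)
from .spectrum import classify_substitution
from .variants import VariantCall

__all__ = [
    "EnrichmentResult",
    "opportunity_window",
    "fisher_one_sided",
    "mutation_load",
    "compute_enrichment",
    "cohort_enrichment",
    "benjamini_hochberg",
    "write_enrichment_results",
]


@dataclass
class EnrichmentResult:
    sample: str
    m_motif: int
    m_class: int
    x_motif: int
    x_class: int
    enrichment: float | None   # None when undefined; math.inf when x_motif=0 < m_motif
    p: float | None
    load: float | None
    q: float | None = None
    flags: tuple = ()

    @property
    def significant(self) -> bool | None:
        if self.p is None or self.enrichment is None:
            return None
        return self.enrichment > 1 and self.p < 0.05


def fisher_one_sided(m_motif: int, m_class: int, x_motif: int, x_class: int
                     ) -> float:
    """One-sided Fisher's exact p for motif over-representation among
    mutations relative to contexts.

    Equals the upper hypergeometric tail P(X >= m_motif) with population
    m_class + x_class, m_motif + x_motif successes, and m_class draws.
    A degenerate table (any zero margin) carries no enrichment evidence
    and returns 1.
    """
    for name, val in (("m_motif", m_motif), ("m_class", m_class),
                      ("x_motif", x_motif), ("x_class", x_class)):
        if val < 0:
            raise ValueError(f"{name} must be non-negative, got {val}")
    if m_motif > m_class or x_motif > x_class:
        raise ValueError("motif counts cannot exceed class counts")
    n_total = m_class + x_class
    k_motif = m_motif + x_motif
    k_rest = n_total - k_motif
    if m_class == 0 or x_class == 0 or k_motif == 0 or k_rest == 0:
        return 1.0
    p = float(hypergeom.sf(m_motif - 1, n_total, k_motif, m_class))
    return min(max(p, 5e-324), 1.0)


def mutation_load(m_motif: int, enrichment: float) -> float:
    """Motif mutations attributable to the signature:
    m_motif * (E - 1) / E, floored at 0 for E <= 1."""
    if enrichment is None:
        raise ValueError("enrichment is undefined; load cannot be computed")
    if enrichment <= 0:
        if enrichment < 0:
            raise ValueError(f"enrichment must be positive, got {enrichment}")
        return 0.0
    if math.isinf(enrichment):
        return float(m_motif)
    return max(0.0, m_motif * (enrichment - 1.0) / enrichment)


def opportunity_window(genome: ReferenceGenome, contig: str, pos: int,
                       flank: int = 20) -> str:
    """The +/-flank window around a mutated position with the mutated
    base itself masked to N, for opportunity counting."""
    seq, offset = window(genome, contig, pos, flank)
    return seq[:offset] + "N" + seq[offset + 1:]


def _class_calls(calls, motif: MotifSpec):
    out = []
    for c in calls:
        if not c.is_snv:
            raise ValueError(f"non-SNV call {c.ref}>{c.alt}; filter first")
        if classify_substitution(c.ref, c.alt) == motif.substitution:
            out.append(c)
    return out


def compute_enrichment(calls, genome: ReferenceGenome,
                       motif: MotifSpec = GCN_TO_A, flank: int = 20,
                       sample: str | None = None,
                       context_source: str = "windows") -> EnrichmentResult:
    """Motif enrichment for one sample's filtered SNVs.

    ``context_source`` selects the opportunity denominator: ``windows``
    (default) counts motif/class occurrences in the +/-flank windows
    around each class mutation, with the mutated base masked to N;
    ``genome`` counts them once over the whole reference.
    """
    if context_source not in ("windows", "genome"):
        raise ValueError(f"unknown context_source {context_source!r}")
    calls = list(calls)
    name = sample if sample is not None else (calls[0].sample if calls else "")
    cls_calls = _class_calls(calls, motif)
    m_class = len(cls_calls)
    if m_class == 0:
        return EnrichmentResult(sample=name, m_motif=0, m_class=0,
                                x_motif=0, x_class=0, enrichment=None,
                                p=None, load=None, flags=("no_class_mutations",))

    m_motif = 0
    windows = []
    for call in cls_calls:
        seq = genome.sequence(call.contig)
        if motif.site_matches(seq, call.pos - 1):
            m_motif += 1
        windows.append(opportunity_window(genome, call.contig, call.pos, flank))
    if context_source == "windows":
        x_motif, x_class = count_contexts(windows, motif)
    else:
        x_motif, x_class = count_contexts(list(genome.contigs.values()), motif)

    flags = []
    if x_motif == 0:
        if m_motif > 0:
            enrichment = math.inf
            flags.append("infinite_enrichment")
        else:
            enrichment = None
            flags.append("no_motif_opportunity")
    else:
        enrichment = (m_motif / m_class) / (x_motif / x_class)
    p = fisher_one_sided(m_motif, m_class, x_motif, x_class)
    load = mutation_load(m_motif, enrichment) if enrichment is not None else None
    return EnrichmentResult(sample=name, m_motif=m_motif, m_class=m_class,
                            x_motif=x_motif, x_class=x_class,
                            enrichment=enrichment, p=p, load=load,
                            flags=tuple(flags))


def benjamini_hochberg(results: list[EnrichmentResult]) -> None:
    """Attach BH-adjusted q-values in place (results with undefined p
    are left untouched and excluded from the adjustment)."""
    from statsmodels.stats.multitest import multipletests

    defined = [r for r in results if r.p is not None]
    if not defined:
        return
    _, qvals, _, _ = multipletests([r.p for r in defined], method="fdr_bh")
    for r, q in zip(defined, qvals):
        r.q = float(q)


def cohort_enrichment(calls_by_sample: dict, genome: ReferenceGenome,
                      motif: MotifSpec = GCN_TO_A, flank: int = 20,
                      mode: str = "per-sample", adjust: bool = False,
                      context_source: str = "windows"
                      ) -> list[EnrichmentResult]:
    """Enrichment for a cohort.

    ``per-sample`` returns one result per isolate (optionally with BH
    adjustment across isolates); ``pooled`` concatenates all calls into
    a single group-level result.
    """
    if mode == "pooled":
        pooled = [c for calls in calls_by_sample.values() for c in calls]
        return [compute_enrichment(pooled, genome, motif, flank,
                                   sample="pooled",
                                   context_source=context_source)]
    if mode != "per-sample":
        raise ValueError(f"unknown mode {mode!r}")
    results = [compute_enrichment(calls, genome, motif, flank, sample=s,
                                  context_source=context_source)
               for s, calls in calls_by_sample.items()]
    if adjust:
        benjamini_hochberg(results)
    return results


def write_enrichment_results(results: list[EnrichmentResult],
                             tsv_path=None, json_path=None) -> None:
    rows = []
    for r in results:
        row = asdict(r)
        row["flags"] = ";".join(r.flags)
        rows.append(row)
    if tsv_path is not None:
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        from pathlib import Path
        Path(json_path).write_text(json.dumps(rows, indent=2) + "\n")
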
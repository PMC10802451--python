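"""Motif enrichment, Fisher testing and attributable load."""

import math
from math import comb

import numpy as np
import pytest

from mutmotif.refgenome import GCN_TO_A, MotifSpec, ReferenceGenome
from mutmotif.trims import (benjamini_hochberg, cohort_enrichment,
                            compute_enrichment, fisher_one_sided,
                            mutation_load, opportunity_window)
from mutmotif.variants import VariantCall

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) for the 2x2 table [[a,b],[c,d]] at fixed margins, by
    direct summation of hypergeometric point probabilities."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    total = comb(n, row1)
    acc = 0
    for k in range(a, min(row1, col1) + 1):
        acc += comb(col1, k) * comb(n - col1, row1 - k)
    return acc / total


def vc(pos, ref, alt, sample="S1", contig="chr1", vaf=1.0):
    return VariantCall(contig, pos, ref, alt, vaf, sample)


class TestFisherOneSided:
    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            m_class = int(rng.integers(1, 25))
            x_class = int(rng.integers(1, 25))
            m_motif = int(rng.integers(0, m_class + 1))
            x_motif = int(rng.integers(0, x_class + 1))
            p = fisher_one_sided(m_motif, m_class, x_motif, x_class)
            expected = hypergeom_tail_oracle(m_motif, m_class - m_motif,
                                             x_motif, x_class - x_motif)
            assert p == pytest.approx(expected, rel=1e-9)

    def test_matches_scipy_fisher(self, rng):
        from scipy.stats import fisher_exact

        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            p = fisher_one_sided(int(a), int(a + b), int(c), int(c + d))
            _, expected = fisher_exact([[a, b], [c, d]], alternative="greater")
            assert p == pytest.approx(expected, rel=1e-8)

    def test_zero_motif_mutations_gives_one(self):
        assert fisher_one_sided(0, 10, 50, 100) == 1.0

    def test_degenerate_margins_give_one(self):
        assert fisher_one_sided(0, 0, 5, 10) == 1.0
        assert fisher_one_sided(0, 10, 0, 0) == 1.0
        assert fisher_one_sided(10, 10, 100, 100) == 1.0  # all motif

    def test_monotone_in_m_motif(self):
        ps = [fisher_one_sided(m, 10, 100, 1000) for m in range(11)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            fisher_one_sided(5, 3, 0, 10)
        with pytest.raises(ValueError):
            fisher_one_sided(-1, 3, 0, 10)


class TestMutationLoad:
    @pytest.mark.parametrize("m,e,expected", [
        (10, 2.0, 5.0), (10, 1.0, 0.0), (8, 4.0, 6.0), (0, 7.0, 0.0),
        (10, 0.5, 0.0),            # depletion floors at zero
        (10, math.inf, 10.0),      # limit: all motif mutations attributable
    ])
    def test_formula(self, m, e, expected):
        assert mutation_load(m, e) == pytest.approx(expected)

    def test_monotone_and_bounded(self):
        loads = [mutation_load(10, e) for e in np.linspace(1.0, 50.0, 60)]
        assert all(b >= a for a, b in zip(loads, loads[1:]))
        assert all(0 <= v <= 10 for v in loads)

    def test_undefined_enrichment_rejected(self):
        with pytest.raises(ValueError):
            mutation_load(10, None)
        with pytest.raises(ValueError):
            mutation_load(10, -1.0)


class TestOpportunityWindow:
    def test_center_masked(self):
        g = ReferenceGenome({"c": "TAGCATA"})
        assert opportunity_window(g, "c", 4, flank=2) == "AGNAT"


class TestComputeEnrichment:
    def test_enrichment_arithmetic(self):
        # fabricated counts through the public formula path
        m_motif, m_class, x_motif, x_class = 8, 10, 100, 1000
        e = (m_motif / m_class) / (x_motif / x_class)
        assert e == pytest.approx(8.0)

    def test_single_motif_mutation_hand_checked(self):
        g = ReferenceGenome({"c": "TAGCATA"})
        res = compute_enrichment([vc(4, "C", "A", contig="c")], g, flank=2)
        # the only class mutation sits in gCn; its masked window AGNAT
        # retains one G (class) and no motif occurrence
        assert (res.m_motif, res.m_class) == (1, 1)
        assert (res.x_motif, res.x_class) == (0, 1)
        assert res.enrichment == math.inf
        assert "infinite_enrichment" in res.flags
        assert res.load == 1.0
        assert 0 < res.p <= 1

    def test_no_class_mutations_flagged_undefined(self):
        g = ReferenceGenome({"c": "TAGCATA"})
        res = compute_enrichment([vc(2, "A", "G", contig="c")], g)
        assert res.m_class == 0
        assert res.enrichment is None and res.p is None and res.load is None
        assert "no_class_mutations" in res.flags

    def test_reverse_strand_motif_mutation_counted(self):
        # G with 3' C: gCn on the reverse strand
        g = ReferenceGenome({"c": "TTGCATT"})
        res = compute_enrichment([vc(3, "G", "T", contig="c")], g, flank=3)
        assert (res.m_motif, res.m_class) == (1, 1)

    def test_strand_symmetry_random_fixtures(self, rng):
        from mutmotif.synthetic_data import generate_genome

        for seed in range(12):
            g = generate_genome(600, 0.4, seed=seed)
            seq = g.contigs["chr1"]
            L = len(seq)
            positions = [int(p) + 1 for p in rng.choice(L, 12, replace=False)]
            alts = {"C": "A", "G": "T", "A": "T", "T": "A"}
            calls = [vc(p, seq[p - 1], alts[seq[p - 1]]) for p in positions]
            flipped = g.reverse_complemented()
            fcalls = [vc(L - c.pos + 1, COMP[c.ref], COMP[c.alt])
                      for c in calls]
            r1 = compute_enrichment(calls, g)
            r2 = compute_enrichment(fcalls, flipped)
            assert (r1.m_motif, r1.m_class, r1.x_motif, r1.x_class) == \
                   (r2.m_motif, r2.m_class, r2.x_motif, r2.x_class)
            assert r1.p == pytest.approx(r2.p)


class TestCohortEnrichment:
    def test_pooled_equals_concatenation(self, random_genome):
        seq = random_genome.contigs["chr1"]
        cs = [i + 1 for i, b in enumerate(seq) if b == "C"]
        calls = {"S1": [vc(p, "C", "A", "S1") for p in cs[10:30]],
                 "S2": [vc(p, "C", "A", "S2") for p in cs[40:70]]}
        pooled = cohort_enrichment(calls, random_genome, mode="pooled")[0]
        direct = compute_enrichment(calls["S1"] + calls["S2"], random_genome)
        assert (pooled.m_motif, pooled.m_class, pooled.x_motif,
                pooled.x_class) == (direct.m_motif, direct.m_class,
                                    direct.x_motif, direct.x_class)

    def test_bh_preserves_p_ordering(self, random_genome):
        seq = random_genome.contigs["chr1"]
        cs = [i + 1 for i, b in enumerate(seq) if b in "CG"]
        rng = np.random.default_rng(5)
        calls = {}
        for s in range(6):
            pos = rng.choice(len(cs), 25, replace=False)
            calls[f"S{s}"] = [
                vc(cs[i], seq[cs[i] - 1],
                   "A" if seq[cs[i] - 1] == "C" else "T", f"S{s}")
                for i in pos]
        results = cohort_enrichment(calls, random_genome, adjust=True)
        defined = [r for r in results if r.p is not None]
        assert defined, "fixture produced no testable samples"
        pairs = sorted((r.p, r.q) for r in defined)
        qs = [q for _, q in pairs]
        assert all(b >= a - 1e-12 for a, b in zip(qs, qs[1:]))
        assert all(r.q >= r.p for r in defined)


def test_custom_motif_spec_flows_through():
    # tCw (APOBEC-style) on a toy sequence: T C A -> mutated C with 5' t, 3' w
    m = MotifSpec("tCw", "T")
    g = ReferenceGenome({"c": "ATCAAGTCTA"})
    res = compute_enrichment([vc(3, "C", "T", contig="c")], g, motif=m,
                             flank=4)
    assert res.m_motif == 1 and res.m_class == 1
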
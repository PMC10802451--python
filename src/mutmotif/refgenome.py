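"""Reference genome container and strand-aware sequence/motif queries.

All downstream statistics interpret substitutions against a reference
genome.  This module loads FASTA references into memory, provides
reverse-complementation and flanking-window extraction, and counts
double-stranded occurrences of a short mutation motif (e.g. ``gCn``)
and of its mutated-base class (e.g. all C/G positions) inside those
windows.  Coordinates are 1-based and fully closed, matching VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "ReferenceGenome",
    "MotifSpec",
    "GCN_TO_A",
    "load_fasta",
    "reverse_complement",
    "window",
    "count_contexts",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC nucleotide codes -> the set of concrete bases they stand for.
# An 'N' in the *genome* never matches any motif position (including 'n'):
# an unknown base is not evidence of motif opportunity.
_IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                                  "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


class GenomeLoadError(ValueError):
    """Raised when a FASTA reference cannot be loaded or validated."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the A,C,G,T,N alphabet."""
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"illegal base(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """Ordered map of contig name -> uppercase DNA sequence."""

    contigs: dict[str, str] = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def sequence(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None

    def base(self, contig: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        seq = self.sequence(contig)
        if not 1 <= pos <= len(seq):
            raise IndexError(
                f"position {pos} outside contig {contig!r} (length {len(seq)})"
            )
        return seq[pos - 1]

    def reverse_complemented(self) -> "ReferenceGenome":
        """A new genome with every contig reverse-complemented (for
        strand-symmetry checks)."""
        return ReferenceGenome(
            {name: reverse_complement(seq) for name, seq in self.contigs.items()}
        )


def load_fasta(path) -> ReferenceGenome:
    """Load a (multi-record) FASTA file into a :class:`ReferenceGenome`.

    Sequences are uppercased; any character outside {A,C,G,T,N} is a
    load error reporting the contig and 1-based offset.  Duplicate or
    empty contig names are rejected, as is an empty file.
    """
    contigs: dict[str, str] = {}
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        name = record.id
        if not name:
            raise GenomeLoadError("contig with empty name")
        if name in contigs:
            raise GenomeLoadError(f"duplicate contig name {name!r}")
        seq = str(record.seq).upper()
        for offset, ch in enumerate(seq, start=1):
            if ch not in _VALID_BASES:
                raise GenomeLoadError(
                    f"illegal character {ch!r} in contig {name!r} at offset {offset}"
                )
        contigs[name] = seq
    if n_records == 0:
        raise GenomeLoadError(f"no FASTA records found in {path}")
    return ReferenceGenome(contigs)


def window(genome: ReferenceGenome, contig: str, pos: int, flank: int = 20
           ) -> tuple[str, int]:
    """Subsequence within ``flank`` bp of a 1-based position.

    Returns ``(sequence, center_offset)`` where ``center_offset`` is the
    0-based index of ``pos`` inside the returned sequence.  The window is
    truncated at contig ends, so its length is at most ``2*flank + 1``.
    """
    seq = genome.sequence(contig)
    if not 1 <= pos <= len(seq):
        raise IndexError(
            f"position {pos} outside contig {contig!r} (length {len(seq)})"
        )
    start = max(1, pos - flank)
    end = min(len(seq), pos + flank)
    return seq[start - 1:end], pos - start


@dataclass(frozen=True)
class MotifSpec:
    """A single-base mutation motif such as gCn -> A.

    ``pattern`` has exactly one uppercase character — the mutated base —
    with lowercase IUPAC codes for context (``n`` = any base).  Purine-
    centered input is folded onto the pyrimidine strand on construction,
    so the canonical pattern always has C or T at the mutated position.
    """

    pattern: str
    to_base: str

    def __post_init__(self):
        uppers = [i for i, ch in enumerate(self.pattern) if ch.isupper()]
        if len(uppers) != 1:
            raise ValueError(
                f"pattern {self.pattern!r} must have exactly one uppercase position"
            )
        for ch in self.pattern:
            if ch.upper() not in _IUPAC:
                raise ValueError(f"unknown IUPAC code {ch!r} in pattern")
        if self.to_base not in "ACGT":
            raise ValueError(f"alternate base must be one of A,C,G,T, got {self.to_base!r}")
        if self.pattern[uppers[0]] in "AG":
            # fold onto the pyrimidine strand
            folded = self.pattern.translate(_IUPAC_COMPLEMENT)[::-1]
            object.__setattr__(self, "pattern", folded)
            object.__setattr__(self, "to_base",
                               self.to_base.translate(_COMPLEMENT))
        if self.from_base == self.to_base:
            raise ValueError("alternate base equals the mutated base")

    @property
    def center_index(self) -> int:
        return next(i for i, ch in enumerate(self.pattern) if ch.isupper())

    @property
    def from_base(self) -> str:
        return self.pattern[self.center_index]

    @property
    def substitution(self) -> str:
        """Pyrimidine-centered class label, e.g. ``C>A``."""
        return f"{self.from_base}>{self.to_base}"

    @property
    def rc_pattern(self) -> str:
        """The pattern as read on the forward strand when the motif sits
        on the reverse strand (e.g. ``nGc`` for ``gCn``)."""
        return self.pattern.translate(_IUPAC_COMPLEMENT)[::-1]

    def _matches_at(self, seq: str, start: int, pattern: str) -> bool:
        if start < 0 or start + len(pattern) > len(seq):
            return False
        for ch, base in zip(pattern, seq[start:start + len(pattern)]):
            if base == "N" or base not in _IUPAC[ch.upper()]:
                return False
        return True

    def count_occurrences(self, seq: str) -> int:
        """Double-stranded motif occurrences in ``seq``: forward matches
        of the pattern plus forward matches of its reverse complement."""
        k = len(self.pattern)
        n = 0
        for start in range(len(seq) - k + 1):
            if self._matches_at(seq, start, self.pattern):
                n += 1
            if self._matches_at(seq, start, self.rc_pattern):
                n += 1
        return n

    def count_class_bases(self, seq: str) -> int:
        """Occurrences of the mutated-base class on either strand: for a
        C-centered motif, the number of C plus the number of G."""
        return seq.count(self.from_base) + seq.count(
            self.from_base.translate(_COMPLEMENT))

    def site_matches(self, seq: str, index: int) -> bool:
        """Whether the base at 0-based ``index`` sits in the motif,
        strand-aware: a C with the pattern context read forward, or a G
        with the reverse-complement pattern context."""
        base = seq[index] if 0 <= index < len(seq) else None
        if base == self.from_base:
            return self._matches_at(seq, index - self.center_index, self.pattern)
        if base == self.from_base.translate(_COMPLEMENT):
            rc_center = len(self.pattern) - 1 - self.center_index
            return self._matches_at(seq, index - rc_center, self.rc_pattern)
        return False


#: Default motif: C->A where the mutated cytosine has a 5' guanine
#: (equivalently G->T with a 3' cytosine on the other strand).
GCN_TO_A = MotifSpec("gCn", "A")


def count_contexts(windows, motif: MotifSpec) -> tuple[int, int]:
    """Total double-stranded (motif, class) opportunity counts over a
    list of windows.

    Windows are counted with multiplicity: overlapping windows around
    nearby mutations each contribute their own bases.  Returns
    ``(x_motif, x_class)``; empty input gives ``(0, 0)``.
    """
    x_motif = 0
    x_class = 0
    for w in windows:
        x_motif += motif.count_occurrences(w)
        x_class += motif.count_class_bases(w)
    return x_motif, x_class
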
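"""GC% concordance between a gene and its host genome.

A gene acquired by lateral transfer from a donor with a different genomic
GC% retains the donor's base composition for a long time, so a gene whose
GC% matches its own genome — while candidate donor genomes differ
substantially — argues against lateral transfer. This module computes
GC% (ambiguous N bases excluded from the denominator) and applies a
simple concordance test with a configurable tolerance (default 3
percentage points; "similar GC%" has no canonical numeric definition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .records import SequenceRecord

GC_TOLERANCE = 3.0

_VALID = set("ACGTN")


def gc_percent(nt: SequenceRecord | str) -> float:
    """GC% of a nucleotide sequence: 100·(G+C)/(A+C+G+T), N excluded.

    Case-insensitive; raises on empty/all-N sequences or letters outside
    {A, C, G, T, N}.
    """
    seq = (nt.seq if isinstance(nt, SequenceRecord) else nt).upper()
    sid = nt.id if isinstance(nt, SequenceRecord) else "<sequence>"
    if not seq:
        raise ValidationError(f"{sid}: empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ValidationError(f"{sid}: invalid nucleotides {sorted(bad)}")
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise ValidationError(f"{sid}: all bases are N; GC%% undefined")
    return 100.0 * (seq.count("G") + seq.count("C")) / denom


@dataclass(frozen=True)
class GCRecord:
    """Gene-vs-genome GC comparison for one strain."""

    label: str
    gene_gc: float
    genome_gc: float
    tolerance: float = GC_TOLERANCE

    def __post_init__(self):
        for v, name in ((self.gene_gc, "gene_gc"), (self.genome_gc, "genome_gc")):
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{self.label}: {name} outside [0, 100]")

    @property
    def delta(self) -> float:
        return self.gene_gc - self.genome_gc

    @property
    def concordant(self) -> bool:
        return abs(self.delta) <= self.tolerance


def gc_concordance(
    records: Iterable[GCRecord | tuple],
    tolerance: float = GC_TOLERANCE,
    groups: Mapping[str, str] | None = None,
) -> dict:
    """Per-record concordance verdicts and a cohort-level conclusion.

    ``records`` are GCRecords or ``(label, gene_gc, genome_gc)`` tuples.
    With ``groups`` mapping labels to subclades, the conclusion is
    ``"LGT not supported"`` only when every gene matches its own genome
    *and* the subclade mean genome GC%s differ by more than the
    tolerance (otherwise concordance carries no signal); without groups,
    or with indistinguishable groups, the conclusion is left open.
    """
    recs: list[GCRecord] = []
    for r in records:
        if isinstance(r, GCRecord):
            recs.append(
                GCRecord(r.label, r.gene_gc, r.genome_gc, tolerance)
            )
        else:
            label, gene, genome = r
            recs.append(GCRecord(label, float(gene), float(genome), tolerance))
    if not recs:
        raise ValidationError("gc_concordance requires at least one record")
    all_concordant = all(r.concordant for r in recs)
    group_gap = None
    if groups:
        means: dict[str, list[float]] = {}
        for r in recs:
            g = groups.get(r.label)
            if g is not None:
                means.setdefault(g, []).append(r.genome_gc)
        if len(means) >= 2:
            avgs = sorted(sum(v) / len(v) for v in means.values())
            group_gap = avgs[-1] - avgs[0]
    if all_concordant and group_gap is not None and group_gap > tolerance:
        conclusion = "LGT not supported"
    elif not all_concordant:
        conclusion = "discordant records present; LGT not excluded"
    else:
        conclusion = "inconclusive"
    return {
        "records": recs,
        "all_concordant": all_concordant,
        "group_genome_gc_gap": group_gap,
        "tolerance": tolerance,
        "conclusion": conclusion,
    }


def records_from_sequences(
    pairs: Sequence[tuple[str, SequenceRecord | str, SequenceRecord | str]],
    tolerance: float = GC_TOLERANCE,
) -> list[GCRecord]:
    """Build GCRecords from (label, gene sequence, genome sequence) triples."""
    return [
        GCRecord(label, gc_percent(gene), gc_percent(genome), tolerance)
        for label, gene, genome in pairs
    ]
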
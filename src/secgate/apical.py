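"""Apical-region annotation and top-gate classification of secretin sequences.

Secretins of the bacterial type II secretion system carry a variable
"apical region" bracketed by two short, strongly conserved motifs:
``[QN]W`` on the N-terminal side and ``[AVMG]LI[VILMF]`` on the C-terminal
side. The length of that region predicts whether the assembled channel
carries an optional apical constriction (the "top gate"): regions of 80
residues or more do, shorter regions do not.

This module locates the anchor motifs in a single sequence (no multiple
sequence alignment required), extracts the region strictly between them,
measures its length and charged/polar composition, applies the >=80-residue
top-gate rule, and summarises cohorts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AnchorNotFoundError, ValidationError
from .records import SequenceRecord

logger = logging.getLogger(__name__)

#: Default anchor motifs (degenerate classes, one bracketed set per position).
LEFT_MOTIF = "[QN]W"
RIGHT_MOTIF = "[AVMG]LI[VILMF]"

#: Apical-region length at or above which a top gate is called.
TOP_GATE_THRESHOLD = 80

#: Sanity ceiling on region length used to disambiguate multiple anchor
#: matches (observed natural maximum is 101 aa).
MAX_REGION_LENGTH = 150

#: Residue classes used for composition fractions. 'X' and other
#: non-standard letters belong to no class but still count in the
#: denominator.
DEFAULT_CLASSES = {
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
    "polar": frozenset("STNQYCW"),
}


def parse_motif(motif: str) -> list[frozenset]:
    """Expand a degenerate motif string into one residue set per position.

    ``"[QN]W"`` -> ``[{Q,N}, {W}]``. Brackets enclose alternatives; bare
    letters are singletons.
    """
    positions: list[frozenset] = []
    i = 0
    while i < len(motif):
        c = motif[i]
        if c == "[":
            j = motif.index("]", i)
            if j == i + 1:
                raise ValidationError(f"empty class in motif {motif!r}")
            positions.append(frozenset(motif[i + 1 : j]))
            i = j + 1
        elif c.isalpha():
            positions.append(frozenset(c))
            i += 1
        else:
            raise ValidationError(f"bad character {c!r} in motif {motif!r}")
    if not positions:
        raise ValidationError("empty motif")
    return positions


def motif_matches(seq: str, motif: str) -> list[int]:
    """All 0-based start positions where ``motif`` matches ``seq`` (overlaps allowed)."""
    classes = parse_motif(motif)
    k = len(classes)
    return [
        i
        for i in range(len(seq) - k + 1)
        if all(seq[i + p] in classes[p] for p in range(k))
    ]


@dataclass(frozen=True)
class AnchorPair:
    """1-based inclusive coordinates of the left and right anchor matches."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int

    def __post_init__(self):
        if not self.left_end < self.right_start:
            raise ValidationError("left anchor must end before right anchor starts")

    @property
    def region_start(self) -> int:
        return self.left_end + 1

    @property
    def region_end(self) -> int:
        return self.right_start - 1

    @property
    def region_length(self) -> int:
        return self.right_start - self.left_end - 1


def find_anchors(
    seq: SequenceRecord | str,
    left_motif: str = LEFT_MOTIF,
    right_motif: str = RIGHT_MOTIF,
    max_region: int = MAX_REGION_LENGTH,
) -> AnchorPair:
    """Locate the anchor motif pair bracketing the apical region.

    When several left/right matches exist the pair is chosen by rule:
    among pairs whose bracketed region is at most ``max_region`` residues,
    take the one with the shortest region; ties go to the leftmost left
    anchor, then the leftmost right anchor. If no pair fits under the
    ceiling the globally shortest region wins.

    Raises
    ------
    AnchorNotFoundError
        If the left motif never matches, or no right match lies
        downstream of a left match.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    sid = seq.id if isinstance(seq, SequenceRecord) else "<sequence>"
    if not s:
        raise ValidationError(f"{sid}: empty sequence")
    nl = len(parse_motif(left_motif))
    nr = len(parse_motif(right_motif))
    lefts = motif_matches(s, left_motif)
    if not lefts:
        raise AnchorNotFoundError(f"{sid}: left anchor {left_motif!r} not found", "left")
    rights = motif_matches(s, right_motif)
    # Candidate pairs: right match strictly downstream of the left match.
    pairs = [
        (l, r)
        for l in lefts
        for r in rights
        if r >= l + nl  # region length r - (l + nl) >= 0
    ]
    if not pairs:
        raise AnchorNotFoundError(
            f"{sid}: no right anchor {right_motif!r} downstream of a left anchor",
            "right",
        )

    def key(pair):
        l, r = pair
        return (r - l - nl, l, r)

    within = [p for p in pairs if p[1] - p[0] - nl <= max_region]
    l, r = min(within or pairs, key=key)
    return AnchorPair(
        left_start=l + 1,
        left_end=l + nl,
        right_start=r + 1,
        right_end=r + nr,
    )


def residue_composition(
    region: str, classes: dict[str, frozenset] | None = None
) -> tuple[float, float, float]:
    """Fractions of positively charged, negatively charged and polar residues.

    The denominator is the region length; residues outside all classes
    (including non-standard letters, which are warned about) contribute to
    no numerator. A zero-length region yields ``(0.0, 0.0, 0.0)``.
    """
    classes = classes or DEFAULT_CLASSES
    if len(region) == 0:
        logger.warning("composition requested for zero-length region")
        return (0.0, 0.0, 0.0)
    known = set().union(*classes.values()) | set("ACDEFGHIKLMNPQRSTVWY")
    odd = set(region) - known
    if odd:
        logger.warning("non-standard residues %s counted in no class", sorted(odd))
    n = len(region)
    fp = sum(region.count(a) for a in classes["positive"]) / n
    fn = sum(region.count(a) for a in classes["negative"]) / n
    fq = sum(region.count(a) for a in classes["polar"]) / n
    return (fp, fn, fq)


@dataclass(frozen=True)
class ApicalRegionAnnotation:
    """Measured and classified apical region of one secretin."""

    sequence_id: str
    region_start: int
    region_end: int
    length: int
    frac_positive: float
    frac_negative: float
    frac_polar: float
    top_gate: bool
    threshold_used: int = TOP_GATE_THRESHOLD


def extract_apical_region(
    seq: SequenceRecord,
    anchors: AnchorPair | None = None,
    threshold: int = TOP_GATE_THRESHOLD,
    classes: dict[str, frozenset] | None = None,
    left_motif: str = LEFT_MOTIF,
    right_motif: str = RIGHT_MOTIF,
) -> ApicalRegionAnnotation:
    """Annotate the region strictly between the anchors of one sequence.

    The region is ``[left_end+1, right_start-1]`` (1-based inclusive);
    anchors themselves are excluded. ``top_gate`` is true iff the region
    length is greater than or equal to ``threshold``. A zero-length region
    (anchors abutting) is legal.
    """
    if anchors is None:
        anchors = find_anchors(seq, left_motif, right_motif)
    region = seq.seq[anchors.left_end : anchors.right_start - 1]
    fp, fn, fq = residue_composition(region, classes)
    return ApicalRegionAnnotation(
        sequence_id=seq.id,
        region_start=anchors.region_start,
        region_end=anchors.region_end,
        length=len(region),
        frac_positive=fp,
        frac_negative=fn,
        frac_polar=fq,
        top_gate=len(region) >= threshold,
        threshold_used=threshold,
    )


def annotate_cohort(
    records: Iterable[SequenceRecord], **kwargs
) -> list[ApicalRegionAnnotation]:
    """Annotate every sequence in a cohort (keyword args as for
    :func:`extract_apical_region`)."""
    return [extract_apical_region(r, **kwargs) for r in records]


@dataclass
class CohortSummary:
    """Cohort-level census of apical-region lengths and top-gate calls."""

    n_total: int
    n_top_gated: int
    fraction_top_gated: float
    length_min: int
    length_max: int
    length_histogram: dict = field(default_factory=dict)

    @property
    def percent_top_gated(self) -> float:
        """Top-gated fraction as a percentage, one decimal."""
        return round(100.0 * self.fraction_top_gated, 1)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_total": self.n_total,
            "n_top_gated": self.n_top_gated,
            "fraction_top_gated": self.fraction_top_gated,
            "percent_top_gated": self.percent_top_gated,
            "length_min": self.length_min,
            "length_max": self.length_max,
            "length_histogram": self.length_histogram,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def summarize_cohort(
    annotations: Sequence[ApicalRegionAnnotation], bin_width: int = 5
) -> CohortSummary:
    """Summarise a list of annotations (counts, fraction, length histogram).

    The histogram uses fixed-width bins aligned to multiples of
    ``bin_width`` so identical cohorts always summarise identically.
    """
    if not annotations:
        raise ValidationError("cannot summarise an empty cohort")
    lengths = np.array([a.length for a in annotations])
    n_top = int(sum(a.top_gate for a in annotations))
    lo = int(lengths.min()) // bin_width * bin_width
    hi = (int(lengths.max()) // bin_width + 1) * bin_width
    edges = np.arange(lo, hi + 1, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    hist = {
        f"[{int(edges[i])},{int(edges[i + 1])})": int(c)
        for i, c in enumerate(counts)
    }
    return CohortSummary(
        n_total=len(annotations),
        n_top_gated=n_top,
        fraction_top_gated=n_top / len(annotations),
        length_min=int(lengths.min()),
        length_max=int(lengths.max()),
        length_histogram=hist,
    )


def annotations_to_frame(
    annotations: Sequence[ApicalRegionAnnotation],
) -> pd.DataFrame:
    """Tabulate annotations for TSV export."""
    return pd.DataFrame(
        [
            {
                "sequence_id": a.sequence_id,
                "region_start": a.region_start,
                "region_end": a.region_end,
                "length": a.length,
                "frac_positive": a.frac_positive,
                "frac_negative": a.frac_negative,
                "frac_polar": a.frac_polar,
                "top_gate": a.top_gate,
            }
            for a in annotations
        ]
    )
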
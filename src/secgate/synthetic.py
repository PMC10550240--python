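"""Synthetic inputs with known ground truth for every downstream analysis.

Three families of fixtures are generated, each emulating the statistical
or geometric structure the real analyses assume:

* **Secretin-like protein cohorts** — sequences built as
  ``scaffold + left anchor + apical region + right anchor + scaffold``
  with the apical length drawn from a controlled distribution (default
  uniform on [34, 101] residues, the observed natural range). Anchors are
  planted verbatim ("QW" / "ALIV" by default, any member of the
  degenerate classes ``[QN]W`` / ``[AVMG]LI[VILMF]`` may be configured);
  all random residues are drawn from an alphabet without W and I, which
  makes the planted anchors the *only* motif matches — ground-truth
  boundaries are unambiguous by construction. Substitutions never touch
  anchor positions and never introduce W or I.

* **Cn-symmetric toy channels** — one reference atom per residue per
  chain (a Cβ-equivalent carbon) on rings about the z axis; chain k is
  the exact rotation of chain 0 by 360°/n. A gate is planted as a radial
  inward run of loop residues whose innermost atom sits exactly at the
  gate radius, so the analytic aperture diameter is 2·gate_radius.
  Bridge-compatible residue pairs are planted at ring radii chosen from
  the chord law d = 2·r·sin(π/n); negatives beyond the bridge distance.

* **Coding sequences at a target GC%** — a reverse translation of a
  protein choosing synonymous codons to match a GC target; translation
  always returns the input protein exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .apical import parse_motif
from .errors import ValidationError
from .records import SequenceRecord, write_fasta
from .structure import ATOM_COLUMNS, ChannelStructure

#: Residues used for random scaffold/region positions. W and I are
#: excluded so planted anchors ([QN]W needs a W; [AVMG]LI[VILMF] needs an
#: I) are the unique motif matches in every generated sequence.
RANDOM_ALPHABET = "ACDEFGHKLMNPQRSTVY"

DEFAULT_APICAL_RANGE = (34, 101)


# ---------------------------------------------------------------------------
# secretin-like cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Parameters of a synthetic secretin cohort.

    ``apical_length_sampler`` may be an int (constant length), a
    ``(lo, hi)`` tuple (uniform inclusive) or a callable
    ``rng -> int``.
    """

    n_sequences: int
    apical_length_sampler: int | tuple[int, int] | Callable = DEFAULT_APICAL_RANGE
    scaffold_length_n: int = 60
    scaffold_length_c: int = 60
    substitution_rate: float = 0.0
    left_anchor: str = "QW"
    right_anchor: str = "ALIV"
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 1:
            raise ValidationError("n_sequences must be >= 1")
        if self.scaffold_length_n < 0 or self.scaffold_length_c < 0:
            raise ValidationError("scaffold lengths must be >= 0")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValidationError("substitution_rate must be in [0, 1]")
        for anchor, motif in (
            (self.left_anchor, "[QN]W"),
            (self.right_anchor, "[AVMG]LI[VILMF]"),
        ):
            classes = parse_motif(motif)
            if len(anchor) != len(classes) or any(
                a not in cls for a, cls in zip(anchor, classes)
            ):
                raise ValidationError(
                    f"anchor {anchor!r} is not a member of class {motif}"
                )

    def sample_length(self, rng: np.random.Generator) -> int:
        s = self.apical_length_sampler
        if callable(s):
            length = int(s(rng))
        elif isinstance(s, int):
            length = s
        else:
            lo, hi = s
            length = int(rng.integers(lo, hi + 1))
        if length < 0:
            raise ValidationError("sampled apical length must be >= 0")
        return length


@dataclass
class SyntheticCohort:
    """Generated sequences plus their ground-truth apical annotations."""

    records: list[SequenceRecord]
    truth: pd.DataFrame  # sequence_id, region_start, region_end, length
    spec: CohortSpec

    def write_fasta(self, path: str | Path) -> None:
        write_fasta(self.records, path)

    def write_truth(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(RANDOM_ALPHABET), size=n)) if n else ""


def gen_secretin_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a labeled cohort of secretin-like sequences.

    Every sequence contains exactly one left-anchor and one right-anchor
    motif match; the ground-truth region is strictly between them.
    Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    records, rows = [], []
    for i in range(spec.n_sequences):
        length = spec.sample_length(rng)
        scaffold_n = _random_protein(rng, spec.scaffold_length_n)
        region = _random_protein(rng, length)
        scaffold_c = _random_protein(rng, spec.scaffold_length_c)
        seq = scaffold_n + spec.left_anchor + region + spec.right_anchor + scaffold_c
        if spec.substitution_rate > 0:
            left0 = len(scaffold_n)
            right0 = left0 + len(spec.left_anchor) + length
            anchor_idx = set(range(left0, left0 + len(spec.left_anchor))) | set(
                range(right0, right0 + len(spec.right_anchor))
            )
            chars = list(seq)
            hits = rng.random(len(chars)) < spec.substitution_rate
            for j in np.nonzero(hits)[0]:
                if int(j) not in anchor_idx:
                    chars[j] = rng.choice(list(RANDOM_ALPHABET))
            seq = "".join(chars)
        sid = f"syn{i:05d}"
        records.append(SequenceRecord(id=sid, seq=seq))
        region_start = len(scaffold_n) + len(spec.left_anchor) + 1  # 1-based
        rows.append(
            {
                "sequence_id": sid,
                "region_start": region_start,
                "region_end": region_start + length - 1,
                "length": length,
            }
        )
    return SyntheticCohort(
        records=records,
        truth=pd.DataFrame(
            rows, columns=["sequence_id", "region_start", "region_end", "length"]
        ),
        spec=spec,
    )


def gen_family_cohort(
    family_sizes: Sequence[int],
    apical_lengths: Sequence[int] | None = None,
    seed: int = 0,
    substitution_rate: float = 0.05,
) -> SyntheticCohort:
    """Cohort of sequence families: each family descends from one random
    ancestor by per-site substitution, so within-family identity is high
    and between-family identity is background.

    ``apical_lengths[k]`` fixes the apical length of family k (default:
    alternating 40 / 90 so some families are top-gated).
    """
    if not family_sizes or any(s < 1 for s in family_sizes):
        raise ValidationError("family_sizes must be non-empty positive ints")
    if apical_lengths is None:
        apical_lengths = [40 if k % 2 == 0 else 90 for k in range(len(family_sizes))]
    if len(apical_lengths) != len(family_sizes):
        raise ValidationError("apical_lengths must match family_sizes")
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for k, (size, length) in enumerate(zip(family_sizes, apical_lengths)):
        ancestor = gen_secretin_cohort(
            CohortSpec(
                n_sequences=1,
                apical_length_sampler=int(length),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        base = ancestor.records[0].seq
        t = ancestor.truth.iloc[0]
        left0 = int(t.region_start) - 3  # 0-based start of the "QW" anchor
        right0 = int(t.region_end)  # 0-based start of the "ALIV" anchor
        anchor_idx = set(range(left0, left0 + 2)) | set(range(right0, right0 + 4))
        for m in range(size):
            chars = list(base)
            hits = rng.random(len(chars)) < substitution_rate
            for j in np.nonzero(hits)[0]:
                if int(j) not in anchor_idx:
                    chars[j] = rng.choice(list(RANDOM_ALPHABET))
            sid = f"fam{k}_{m:03d}"
            records.append(SequenceRecord(id=sid, seq="".join(chars), taxon=f"fam{k}"))
            rows.append(
                {
                    "sequence_id": sid,
                    "region_start": int(t.region_start),
                    "region_end": int(t.region_end),
                    "length": int(t.length),
                }
            )
    spec = CohortSpec(n_sequences=len(records), seed=seed)
    return SyntheticCohort(
        records=records,
        truth=pd.DataFrame(
            rows, columns=["sequence_id", "region_start", "region_end", "length"]
        ),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Cn-symmetric toy channels
# ---------------------------------------------------------------------------

@dataclass
class ChannelSpec:
    """Parameters of a Cn-symmetric toy channel.

    Residues carry a single Cβ-equivalent carbon atom. The barrel is a
    vertical column of residues at ``barrel_radius``; the planted gate is
    a horizontal loop of residues running inward to exactly
    ``gate_radius`` at mid-height (plus an optional second, apical gate
    near the top). ``planted_pair_positions`` (barrel residue numbers)
    are moved onto rings whose adjacent-chain chord equals
    ``bridge_distance``; ``planted_negative_positions`` onto rings at
    ``negative_distance``.
    """

    n_chains: int = 15
    barrel_radius: float = 40.0
    gate_radius: float | None = 7.0
    apical_gate_radius: float | None = None
    n_barrel_residues: int = 30
    n_loop_residues: int = 8
    planted_pair_positions: list[int] = field(default_factory=list)
    planted_negative_positions: list[int] = field(default_factory=list)
    bridge_distance: float = 5.0
    negative_distance: float = 12.0
    rise: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_chains < 3:
            raise ValidationError("n_chains must be >= 3")
        if self.barrel_radius <= 0:
            raise ValidationError("barrel_radius must be positive")
        for g in (self.gate_radius, self.apical_gate_radius):
            if g is not None and not 0 <= g < self.barrel_radius:
                raise ValidationError("gate radius must satisfy 0 <= g < barrel_radius")
        if set(self.planted_pair_positions) & set(self.planted_negative_positions):
            raise ValidationError("planted position lists must be disjoint")
        if self.n_barrel_residues < 4:
            raise ValidationError("need >= 4 barrel residues")
        for pos in self.planted_pair_positions + self.planted_negative_positions:
            if not 1 <= pos <= self.n_barrel_residues:
                raise ValidationError(
                    f"planted position {pos} outside barrel residues "
                    f"1..{self.n_barrel_residues}"
                )

    def ring_radius(self, distance: float) -> float:
        """Ring radius whose adjacent-chain chord is ``distance``
        (chord law d = 2·r·sin(π/n))."""
        return distance / (2.0 * math.sin(math.pi / self.n_chains))


@dataclass
class SyntheticChannel:
    """Generated channel plus analytic ground truth."""

    structure: ChannelStructure
    constrictions: pd.DataFrame  # z, diameter (analytic)
    crosslinks: pd.DataFrame  # resnum, ring_radius, distance, bridge_compatible
    spec: ChannelSpec

    def write_truth(self, path: str | Path) -> None:
        self.crosslinks.to_csv(path, sep="\t", index=False)


def gen_cn_channel(spec: ChannelSpec, bridge_threshold: float = 7.0) -> SyntheticChannel:
    """Generate a Cn-symmetric toy channel with analytic gate and
    cross-link ground truth.

    Chain k is chain 0 rotated by 2πk/n about z. The seed only randomises
    the global angular phase — all ground-truth quantities are exact.
    """
    rng = np.random.default_rng(spec.seed)
    phase = float(rng.uniform(0.0, 2.0 * math.pi / spec.n_chains))

    # chain 0 as (resnum, radius, z); barrel column first
    residues: list[tuple[int, float, float]] = [
        (i + 1, spec.barrel_radius, i * spec.rise)
        for i in range(spec.n_barrel_residues)
    ]
    z_top = (spec.n_barrel_residues - 1) * spec.rise
    crosslink_rows = []
    for pos, dist, label in [
        (p, spec.bridge_distance, True) for p in spec.planted_pair_positions
    ] + [(p, spec.negative_distance, False) for p in spec.planted_negative_positions]:
        r = spec.ring_radius(dist)
        for g in (spec.gate_radius, spec.apical_gate_radius):
            if g is not None and r <= g:
                raise ValidationError(
                    f"planted position {pos}: ring radius {r:.2f} Å does not "
                    f"exceed gate radius {g} Å; constriction ground truth "
                    "would be invalidated"
                )
        residues[pos - 1] = (pos, r, residues[pos - 1][2])
        crosslink_rows.append(
            {
                "resnum": pos,
                "ring_radius": r,
                "distance": dist,
                "bridge_compatible": label,
            }
        )

    constriction_rows = []
    next_resnum = spec.n_barrel_residues + 1
    for g, z_frac, tag in [
        (spec.gate_radius, 0.5, "central"),
        (spec.apical_gate_radius, 0.95, "apical"),
    ]:
        if g is None:
            continue
        z_gate = round(z_frac * z_top)
        radii = np.linspace(spec.barrel_radius, g, spec.n_loop_residues)
        for r in radii:
            residues.append((next_resnum, float(r), float(z_gate)))
            next_resnum += 1
        constriction_rows.append({"gate": tag, "z": z_gate, "diameter": 2.0 * g})

    # non-planted barrel residues must sit outside the gate radii too
    rows = []
    for k in range(spec.n_chains):
        theta = phase + 2.0 * math.pi * k / spec.n_chains
        chain_id = chr(ord("A") + k) if k < 26 else f"A{k}"
        for resnum, r, z in residues:
            rows.append(
                {
                    "chain": chain_id,
                    "resnum": resnum,
                    "resname": "ALA",
                    "atom": "CB",
                    "element": "C",
                    "x": r * math.cos(theta),
                    "y": r * math.sin(theta),
                    "z": z,
                }
            )
    structure = ChannelStructure(
        atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS), symmetry_order=spec.n_chains
    )
    crosslinks = pd.DataFrame(
        crosslink_rows, columns=["resnum", "ring_radius", "distance", "bridge_compatible"]
    ).sort_values("resnum").reset_index(drop=True) if crosslink_rows else pd.DataFrame(
        columns=["resnum", "ring_radius", "distance", "bridge_compatible"]
    )
    return SyntheticChannel(
        structure=structure,
        constrictions=pd.DataFrame(constriction_rows, columns=["gate", "z", "diameter"]),
        crosslinks=crosslinks,
        spec=spec,
    )


def gen_hairpin_monomer(
    n_per_strand: int = 6,
    cross_distance: float = 5.0,
    rise: float = 3.3,
    chain: str = "A",
) -> ChannelStructure:
    """Ideal two-stranded antiparallel β-hairpin (Cα trace).

    Strand 1 runs +y, a two-residue turn, strand 2 runs -y offset by
    ``cross_distance`` in x, giving perfect antiparallel register.
    """
    rows = []
    resnum = 1
    for i in range(n_per_strand):
        rows.append((resnum, 0.0, i * rise, 0.0))
        resnum += 1
    top = (n_per_strand - 1) * rise
    for dx in (cross_distance / 3.0, 2.0 * cross_distance / 3.0):
        rows.append((resnum, dx, top + 2.2, 0.0))
        resnum += 1
    for i in range(n_per_strand):
        rows.append((resnum, cross_distance, top - i * rise, 0.0))
        resnum += 1
    atoms = pd.DataFrame(
        [
            {
                "chain": chain,
                "resnum": rn,
                "resname": "GLY",
                "atom": "CA",
                "element": "C",
                "x": x,
                "y": y,
                "z": z,
            }
            for rn, x, y, z in rows
        ],
        columns=ATOM_COLUMNS,
    )
    return ChannelStructure(atoms=atoms, symmetry_order=1)


def gen_helix_monomer(n_residues: int = 14, chain: str = "A") -> ChannelStructure:
    """Ideal α-helix Cα trace (2.3 Å radius, 1.5 Å rise, 100°/residue)."""
    atoms = pd.DataFrame(
        [
            {
                "chain": chain,
                "resnum": i + 1,
                "resname": "ALA",
                "atom": "CA",
                "element": "C",
                "x": 2.3 * math.cos(math.radians(100.0 * i)),
                "y": 2.3 * math.sin(math.radians(100.0 * i)),
                "z": 1.5 * i,
            }
            for i in range(n_residues)
        ],
        columns=ATOM_COLUMNS,
    )
    return ChannelStructure(atoms=atoms, symmetry_order=1)


# ---------------------------------------------------------------------------
# coding sequences at controlled GC%
# ---------------------------------------------------------------------------

def _codon_options() -> dict[str, list[tuple[str, int]]]:
    """Map residue -> [(codon, gc_count)] from the standard genetic code."""
    table = CodonTable.unambiguous_dna_by_id[1]
    options: dict[str, list[tuple[str, int]]] = {}
    for codon, aa in table.forward_table.items():
        gc = sum(1 for b in codon if b in "GC")
        options.setdefault(aa, []).append((codon, gc))
    for aa in options:
        options[aa].sort()
    return options


_CODONS = _codon_options()


def gc_attainable_range(protein: str) -> tuple[float, float]:
    """Min and max GC% attainable by synonymous codon choice."""
    total = 3 * len(protein)
    lo = sum(min(gc for _, gc in _CODONS[a]) for a in protein)
    hi = sum(max(gc for _, gc in _CODONS[a]) for a in protein)
    return 100.0 * lo / total, 100.0 * hi / total


def gen_coding_sequence(
    protein: SequenceRecord | str, target_gc: float, seed: int = 0
) -> SequenceRecord:
    """Reverse-translate ``protein`` choosing codons to match ``target_gc``.

    The realized GC% is within 2 percentage points of the target whenever
    codon degeneracy allows; otherwise a validation error reports the
    attainable range. Translation of the output is exactly the input
    protein; fixed seed, fixed output.
    """
    if isinstance(protein, str):
        protein = SequenceRecord(id="protein", seq=protein)
    aa = protein.seq.upper()
    bad = set(aa) - set(_CODONS)
    if bad:
        raise ValidationError(f"non-standard residues {sorted(bad)} in {protein.id}")
    if not 0.0 <= target_gc <= 100.0:
        raise ValidationError("target_gc must be in [0, 100]")
    rng = np.random.default_rng(seed)
    total_nt = 3 * len(aa)
    # per-position GC counts are contiguous integer ranges for the
    # standard code, so any total in [sum(min), sum(max)] is attainable
    mins = np.array([min(gc for _, gc in _CODONS[a]) for a in aa])
    maxs = np.array([max(gc for _, gc in _CODONS[a]) for a in aa])
    desired = int(round(target_gc / 100.0 * total_nt))
    achieved = int(np.clip(desired, mins.sum(), maxs.sum()))
    realized_pct = 100.0 * achieved / total_nt
    if abs(realized_pct - target_gc) > 2.0:
        lo, hi = gc_attainable_range(aa)
        raise ValidationError(
            f"target GC {target_gc:.1f}% unattainable for {protein.id}; "
            f"attainable range is [{lo:.1f}%, {hi:.1f}%]"
        )
    counts = mins.copy()
    deficit = achieved - int(counts.sum())
    # raise random positions one GC unit at a time
    while deficit > 0:
        room = np.nonzero(counts < maxs)[0]
        step = rng.choice(room, size=min(deficit, len(room)), replace=False)
        counts[step] += 1
        deficit -= len(step)
    codons = []
    for a, c in zip(aa, counts):
        choices = [codon for codon, gc in _CODONS[a] if gc == c]
        codons.append(choices[int(rng.integers(len(choices)))])
    nt = "".join(codons)
    assert str(Seq(nt).translate()) == aa
    return SequenceRecord(id=f"{protein.id}_cds", seq=nt, taxon=protein.taxon)
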
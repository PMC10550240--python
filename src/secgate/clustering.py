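"""All-versus-all similarity clustering and a distance tree for secretin cohorts.

Desk-scale re-implementation of the cohort-reduction step used on large
secretin family downloads: global pairwise alignment (BLOSUM62, affine
gaps, free end gaps), greedy centroid clustering at identity >= 50% and
bidirectional coverage >= 70%, selection of the k largest clusters, and a
neighbor-joining tree over representatives with distance 1 - identity.

The NJ tree is a deliberately simple distance-based stand-in for
maximum-likelihood phylogenetics, which is out of scope here; no
evolutionary-model correction is applied to the distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .errors import ValidationError
from .records import SequenceRecord

logger = logging.getLogger(__name__)

IDENTITY_MIN = 0.50
COVERAGE_MIN = 0.70

#: Affine gap model: a gap of length L is penalised open + (L-1)*extend.
GAP_OPEN = 11.0
GAP_EXTEND = 1.0


def make_aligner(
    matrix: str = "BLOSUM62",
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> Align.PairwiseAligner:
    """Global protein aligner with affine internal gaps and free end gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


@dataclass(frozen=True)
class PairwiseComparison:
    """Identity and coverage of one global pairwise alignment.

    identity: identical aligned columns / aligned columns excluding
    terminal gap columns. coverage_x: columns where both sequences are
    aligned (no gap) / length of x.
    """

    id_a: str
    id_b: str
    identity: float
    coverage_a: float
    coverage_b: float
    score: float

    def swapped(self) -> "PairwiseComparison":
        return PairwiseComparison(
            self.id_b, self.id_a, self.identity, self.coverage_b, self.coverage_a,
            self.score,
        )

    def passes(self, identity_min: float, coverage_min: float) -> bool:
        return (
            self.identity >= identity_min
            and self.coverage_a >= coverage_min
            and self.coverage_b >= coverage_min
        )


def align_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    aligner: Align.PairwiseAligner | None = None,
) -> PairwiseComparison:
    """Globally align two protein sequences and report identity/coverage."""
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a.seq, b.seq)[0]
    ga, gb = str(aln[0]), str(aln[1])
    ncols = len(ga)
    # trim terminal gap columns (free end gaps)
    start = 0
    while start < ncols and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    end = ncols
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    core = range(start, end)
    n_core = end - start
    matches = sum(1 for i in core if ga[i] == gb[i] and ga[i] != "-")
    both = sum(1 for i in range(ncols) if ga[i] != "-" and gb[i] != "-")
    return PairwiseComparison(
        id_a=a.id,
        id_b=b.id,
        identity=matches / n_core if n_core else 0.0,
        coverage_a=both / len(a.seq),
        coverage_b=both / len(b.seq),
        score=float(aln.score),
    )


@dataclass
class SequenceCluster:
    """A centroid and the members it absorbed under the thresholds."""

    centroid_id: str
    member_ids: list[str]
    identity_min: float = IDENTITY_MIN
    coverage_min: float = COVERAGE_MIN

    @property
    def size(self) -> int:
        return len(self.member_ids)


def greedy_cluster(
    seqs: Sequence[SequenceRecord],
    identity_min: float = IDENTITY_MIN,
    coverage_min: float = COVERAGE_MIN,
    aligner: Align.PairwiseAligner | None = None,
) -> list[SequenceCluster]:
    """Greedy centroid clustering at identity/bidirectional-coverage thresholds.

    Sequences are processed longest-first (ties by id); each is compared
    against existing centroids in creation order and joins the first one
    whose comparison passes both thresholds, else founds a new cluster.
    The clusters partition the input; every member satisfies the
    thresholds against its centroid. No reassignment pass is made, so the
    partition depends on this documented order.
    """
    if not seqs:
        raise ValidationError("greedy_cluster requires at least one sequence")
    if aligner is None:
        aligner = make_aligner()
    ordered = sorted(seqs, key=lambda r: (-len(r.seq), r.id))
    by_id = {r.id: r for r in ordered}
    if len(by_id) != len(ordered):
        raise ValidationError("duplicate sequence ids in input")
    clusters: list[SequenceCluster] = []
    for rec in ordered:
        for cluster in clusters:
            cmp = align_pair(by_id[cluster.centroid_id], rec, aligner)
            if cmp.passes(identity_min, coverage_min):
                cluster.member_ids.append(rec.id)
                break
        else:
            clusters.append(
                SequenceCluster(
                    centroid_id=rec.id,
                    member_ids=[rec.id],
                    identity_min=identity_min,
                    coverage_min=coverage_min,
                )
            )
    return clusters


def select_top_clusters(
    clusters: Sequence[SequenceCluster], k: int = 10
) -> list[SequenceCluster]:
    """The k largest clusters by member count (ties by centroid id)."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(clusters):
        logger.warning(
            "requested %d clusters but only %d exist; returning all", k, len(clusters)
        )
    ranked = sorted(clusters, key=lambda c: (-c.size, c.centroid_id))
    return ranked[:k]


def distance_matrix(
    seqs: Sequence[SequenceRecord],
    aligner: Align.PairwiseAligner | None = None,
) -> DistanceMatrix:
    """All-pairs 1 - identity distances."""
    if aligner is None:
        aligner = make_aligner()
    ids = [r.id for r in seqs]
    import numpy as np

    d = np.zeros((len(seqs), len(seqs)))
    for i, j in combinations(range(len(seqs)), 2):
        cmp = align_pair(seqs[i], seqs[j], aligner)
        d[i, j] = d[j, i] = 1.0 - cmp.identity
    return DistanceMatrix(d, ids)


def nj_tree(
    representatives: Sequence[SequenceRecord] | DistanceMatrix,
    aligner: Align.PairwiseAligner | None = None,
) -> TreeNode:
    """Neighbor-joining tree over representative sequences.

    Accepts sequences (distances computed as 1 - identity) or a
    precomputed distance matrix. Negative branch lengths produced by the
    NJ formulas on non-additive data are clamped to zero.
    """
    if isinstance(representatives, DistanceMatrix):
        dm = representatives
    else:
        if len(representatives) < 3:
            raise ValidationError("a tree needs at least 3 sequences")
        dm = distance_matrix(representatives, aligner)
    if dm.shape[0] < 3:
        raise ValidationError("a tree needs at least 3 taxa")
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def clusters_to_frame(
    clusters: Sequence[SequenceCluster],
    seqs: Sequence[SequenceRecord] | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> pd.DataFrame:
    """Cluster table (centroid, member, identity, coverages) for TSV export."""
    by_id = {r.id: r for r in seqs} if seqs else {}
    if aligner is None:
        aligner = make_aligner()
    rows = []
    for c in clusters:
        for m in c.member_ids:
            if m == c.centroid_id or not by_id:
                ident = cov_a = cov_b = 1.0 if m == c.centroid_id else float("nan")
            else:
                cmp = align_pair(by_id[c.centroid_id], by_id[m], aligner)
                ident, cov_a, cov_b = cmp.identity, cmp.coverage_a, cmp.coverage_b
            rows.append(
                {
                    "centroid": c.centroid_id,
                    "member": m,
                    "identity": ident,
                    "coverage_centroid": cov_a,
                    "coverage_member": cov_b,
                }
            )
    return pd.DataFrame(
        rows, columns=["centroid", "member", "identity", "coverage_centroid",
                       "coverage_member"]
    )


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
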
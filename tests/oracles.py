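"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: alignment by
exhaustive enumeration of all global alignments, tree topology by
bipartition comparison, chord lengths by direct coordinate arithmetic.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (gapped_a, gapped_b)."""

    def rec(i, j, ga, gb):
        if i == len(a) and j == len(b):
            yield ga, gb
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, ga + a[i], gb + b[j])
        if i < len(a):
            yield from rec(i + 1, j, ga + a[i], gb + "-")
        if j < len(b):
            yield from rec(i, j + 1, ga + "-", gb + b[j])

    yield from rec(0, 0, "", "")


def score_alignment(
    ga: str, gb: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Score one gapped alignment: BLOSUM62 substitutions, affine internal
    gaps (length L costs open + (L-1)*extend), free end gaps.

    A gap run is terminal (free) when no residue of the gapped sequence
    precedes or follows it.
    """
    score = 0.0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            score += _BLOSUM62[x, y]
    for g in (ga, gb):
        i = 0
        while i < len(g):
            if g[i] == "-":
                j = i
                while j < len(g) and g[j] == "-":
                    j += 1
                internal = any(c != "-" for c in g[:i]) and any(
                    c != "-" for c in g[j:]
                )
                if internal:
                    score -= gap_open + (j - i - 1) * gap_extend
                i = j
            else:
                i += 1
    return score


def identity_coverage(ga: str, gb: str) -> tuple[float, float, float]:
    """Identity (terminal gap columns excluded) and per-sequence coverage
    of one gapped alignment, computed independently of the library."""
    ncols = len(ga)
    start = 0
    while start < ncols and (ga[start] == "-" or gb[start] == "-"):
        start += 1
    end = ncols
    while end > start and (ga[end - 1] == "-" or gb[end - 1] == "-"):
        end -= 1
    core = end - start
    matches = sum(
        1 for i in range(start, end) if ga[i] == gb[i] and ga[i] != "-"
    )
    both = sum(1 for i in range(ncols) if ga[i] != "-" and gb[i] != "-")
    la = sum(1 for c in ga if c != "-")
    lb = sum(1 for c in gb if c != "-")
    return (matches / core if core else 0.0, both / la, both / lb)


def best_alignments(a: str, b: str):
    """Optimal score and the set of optimal alignments by enumeration."""
    best, opts = -float("inf"), []
    for ga, gb in enumerate_alignments(a, b):
        s = score_alignment(ga, gb)
        if s > best + 1e-9:
            best, opts = s, [(ga, gb)]
        elif abs(s - best) <= 1e-9:
            opts.append((ga, gb))
    return best, opts


def tree_bipartitions(tree) -> set[frozenset]:
    """Non-trivial leaf bipartitions of an skbio TreeNode, each encoded as
    the lexicographically smaller side."""
    leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            splits.add(min(side, other, key=sorted))
    return splits
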
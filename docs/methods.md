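# Methods

## Apical-region annotation

Each secretin sequence is scanned independently for the two conserved
anchor motifs, `[QN]W` (left) and `[AVMG]LI[VILMF]` (right), written as
per-position residue classes; `X` and other non-standard letters never
match a class. The apical region is defined **exclusively**: the residues
strictly between the motifs, `[left_end+1, right_start−1]` in 1-based
coordinates. Whether published apical-region lengths include the anchor
residues is not decidable from sequence alone, so the exclusive convention
is a documented package choice, and the top-gate threshold (region length
≥ 80, inclusive) is applied to this definition.

When several left/right matches exist, the pair is chosen by a
deterministic rule: among pairs bracketing a region of at most 150
residues (a sanity ceiling well above the largest naturally observed
region of 101 aa), take the minimal region length; ties go to the
leftmost left anchor, then the leftmost right anchor. If no pair fits
under the ceiling, the rule falls back to the globally minimal region
rather than failing — the ceiling is a disambiguation device, not a
validity constraint. Both the motifs and the ceiling are configurable.

Composition fractions use the classes positive = {K, R, H}, negative =
{D, E}, polar = {S, T, N, Q, Y, C, W} (configurable; no canonical
definition exists). The denominator is the full region length; residues
outside all classes count in no numerator, so the three fractions plus
the unclassified fraction sum exactly to 1. Zero-length regions (anchors
abutting) are legal and report all-zero fractions.

An MSA-guided annotation mode (mapping anchor columns from a reference
alignment) was considered and deliberately not implemented: the
per-sequence scan removes the dependence on an aligner without changing
the census on any cohort whose anchors are genuinely conserved.

## Clustering and trees

Pairwise comparison uses Biopython's global aligner with BLOSUM62,
affine internal gaps and free end gaps. The gap model is: a gap of
length L costs `open + (L−1)·extend` with open = 11 and extend = 1.
Identity is defined as identical aligned columns divided by aligned
columns *excluding terminal gap columns*; coverage of a sequence is the
number of columns aligned residue-to-residue divided by that sequence's
length — "identity" and "coverage" are otherwise ambiguous terms, so both
definitions are fixed here and used consistently by the tests.

Greedy centroid clustering processes sequences longest-first (ties by
id); each sequence joins the first existing centroid (in creation order)
against which it passes identity ≥ 50 % *and* coverage ≥ 70 % in both
directions, else it founds a new cluster. There is no reassignment pass,
so the partition depends on this documented order; every member is
guaranteed to pass the thresholds against its centroid, and the clusters
partition the input. Top-k selection ranks by member count with
lexicographic centroid-id tie-break.

The tree is plain neighbor joining (scikit-bio) on distances 1 − identity
with no evolutionary-model correction — a deliberately simple
distance-based stand-in for maximum-likelihood inference, which is out of
scope. Negative branch lengths arising on non-additive inputs are clamped
to zero. No bootstrap support is computed.

## Gate geometry

The symmetry axis of a Cn channel is estimated from chain centroids: in a
ring assembly they span a plane, so the axis is the least-variance
eigenvector of their covariance, anchored at the all-atom centroid; the
sign convention makes the largest-magnitude component positive. Collinear
centroid geometry (two near-zero eigenvalues) is rejected as ambiguous.

The pore profile is measured **on-axis**: for each z (default step 1 Å,
slab half-width equal to the step), the accessible radius is the minimum
over slab atoms of (radial distance of the atom centre from the axis −
its van der Waals radius), floored at zero; empty slabs record a missing
value, not zero. Van der Waals radii come from a fixed element table
(C 1.70, N 1.55, O 1.52, S 1.80 Å; configurable). This on-axis measure is
exact for Cn-symmetric channels and fully deterministic; it is *not* the
off-axis sphere optimisation of general channel-profiling algorithms and
will overestimate the aperture of strongly asymmetric pores — a
documented limitation. Constrictions are interior local minima of the
diameter below a cutoff, merged within a 3 Å z-window (the tightest one
kept); boundary minima of monotone profiles are not constrictions.

The cross-link scan reports, for each residue number present in all
chains, the minimal inter-chain distance between reference atoms of the
same residue number (Cβ, or Cα for glycine/Cβ-less residues), and calls
the site bridge-compatible when that distance is at most 7.0 Å — a common
disulfide-engineering screen value; no canonical cutoff exists, so it is
a flag with this documented default. "Adjacent" chains are defined by
angular order about the estimated axis, not chain-id order; an all-pairs
mode is available. Residue numbering is taken as author numbering and
assumed congruent across chains.

Hairpin detection is purely Cα-geometric so it works on backbone-only
models: residues belong to a strand segment when consecutive Cα spacings
are peptide-like (2.8–4.3 Å) and the trace is extended
(Cα(i)–Cα(i+3) ≥ 7 Å; ideal strands run near 10 Å, helices near 5 Å).
A hairpin is called when two disjoint segments of ≥ 3 residues within the
query window pair antiparallel: at least two consecutive residues of one
segment find partners in the other at 4.5–6 Å with decreasing partner
index. No hydrogen-bond energy term is used; all tolerances are
parameters.

## GC% concordance

GC% is 100·(G+C)/(A+C+G+T) with N excluded from the denominator;
empty or all-N input is rejected. A gene is concordant with its genome
when |ΔGC| ≤ 3.0 percentage points (default; "similar GC%" has no
canonical quantification, so the tolerance is a flag). The cohort-level
conclusion "LGT not supported" requires *both* that every gene matches
its own genome and that the candidate subclades' mean genome GC%s differ
by more than the tolerance — without that separation concordance carries
no signal and the verdict is "inconclusive".

## Synthetic data: what it emulates and what it does not

The cohort generator plants `scaffold + QW + region + ALIV + scaffold`
with apical lengths drawn uniformly on [34, 101] residues by default (the
observed natural range; any member of the degenerate anchor classes can
be substituted). All random residues are drawn from the 18-letter
alphabet without W and I, which makes the planted anchors the only
possible motif matches — so ground-truth boundaries are exact by
construction, and substitutions (which never touch anchor positions and
never introduce W or I) preserve that guarantee. Consequences: synthetic
sequences underrepresent W and I, have no paralogs, no indels within the
region, and uniform rather than clade-structured length variation.
Passing tests therefore demonstrate correctness of the annotation logic,
not robustness to anchor degeneration in remote homologs.

The family generator derives each family from one random ancestor by
per-site substitution (default rate 0.05), giving within-family identity
near 0.9 and background between-family identity — the regime the
clustering thresholds are meant to separate.

Toy channels are coarse-grained: one Cβ-equivalent carbon per residue per
chain, placed on rings, with chain k an exact rotation of chain 0 by
360°/n (the seed only randomises the global angular phase). The planted
gate is a loop running radially inward to exactly the gate radius, so the
analytic aperture is 2·gate_radius and the measured accessible diameter
is 2·(gate_radius − 1.7 Å). Planted cross-link sites use the chord law
d = 2·r·sin(π/n) to position residues at an exact adjacent-chain
distance; specs whose planted rings would fall inside a gate radius are
rejected, keeping every ground truth analytic. Real side-chain packing,
membrane context and fold geometry are not modelled, so structure tests
validate the geometry code, not biological plausibility of any model.

Coding sequences are reverse-translated with per-position codon GC counts
raised from their minimum one unit at a time at seeded random positions
until the target GC is met (per-residue attainable GC counts form
contiguous integer ranges in the standard code, so every total in the
attainable range is reachable); targets outside the attainable range ± 2
points are rejected with the range reported. Translation of the output
equals the input protein for every seed. Codon-usage bias of real genomes
is not emulated.

## Problem sizes and numerical choices

Default analysis sizes used throughout the tests and the acceptance
script — 70-sequence census cohorts, 12-sequence clustering cohorts,
100 random channel specs, 100 random 4-taxon matrices, 100 random
proteins — are the package's chosen desk-scale study conditions: large
enough for the binomial and geometric checks to be meaningful, small
enough to run in seconds. Floating-point tolerances: exact geometric
identities are checked to 1e-6 Å or better; closed-form branch lengths to
1e-9. Determinism: every generator consumes a single integer seed through
one `numpy` Generator per call; workflow reruns with the same
configuration are byte-identical.

## Known limitations

* The on-axis aperture underestimates nothing and overestimates off-axis
  bottlenecks; it is adequate only for approximately Cn-symmetric pores.
* Greedy clustering is order-dependent by design; it reproduces the
  thresholds, not any particular external clustering engine's heuristics.
* NJ trees carry no support values and no substitution-model correction.
* The top-gate rule is a length threshold on an exclusively defined
  region; sequences whose anchors are themselves degenerate beyond the
  two motif classes will fail annotation with an explicit error rather
  than being guessed.
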
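# secgate

Sequence- and structure-based analysis of the gates of bacterial secretins
— the giant Cn-symmetric outer-membrane channels (typically 12–15
subunits) through which type II secretion systems export folded effector
proteins.

Two structural features regulate what passes through a secretin: the
**central gate**, a horizontal closure formed by loops that converge from
every subunit toward the channel axis, and an optional **top gate**, an
apical constriction built from one antiparallel β-strand pair per subunit.
Whether a secretin carries a top gate can be predicted from sequence
alone: the variable "apical region" between two strongly conserved motifs,
`[QN]W` on the N-terminal side and `[AVMG]LI[VILMF]` on the C-terminal
side, is ≥ 80 residues long in top-gated secretins and shorter otherwise.

`secgate` is aimed at microbiologists and structural bioinformaticians who
want to apply these analyses to their own secretin sequences and channel
models. It provides:

* **Apical-region annotation** — per-sequence motif anchoring (no MSA
  needed), region extraction, length and charged/polar composition, and
  the ≥ 80-residue top-gate call, with cohort summaries.
* **Cohort clustering and trees** — all-vs-all global alignment
  (BLOSUM62, affine gaps), greedy centroid clustering at identity ≥ 50 %
  and bidirectional coverage ≥ 70 %, top-k cluster selection, and a
  neighbor-joining tree over representatives (distance 1 − identity).
* **Gate geometry** — for PDB/mmCIF channel structures: symmetry-axis
  estimation, an accessible pore-radius profile along the axis,
  constriction detection, a disulfide cross-link site scan (minimal
  inter-chain Cβ–Cβ distance per residue, default 7 Å compatibility
  threshold), and Cα-geometric detection of the top-gate β-hairpin.
* **GC% concordance** — gene-vs-genome GC% comparison used to exclude
  lateral gene transfer between secretin subclades.
* **Synthetic data** — generators for secretin-like cohorts with planted
  apical regions, Cn-symmetric toy channels with analytic gate and
  cross-link ground truth, and coding sequences at a controlled GC%, so
  every analysis is testable without downloads.

## Worked example

Generate a 12-sequence cohort of three sequence families (one family
planted with 90-residue apical regions, hence top-gated), then run the
cohort workflow:

```python
from secgate import RunConfig, gen_family_cohort, run_cohort_workflow

cohort = gen_family_cohort([5, 4, 3], apical_lengths=[40, 90, 45], seed=21)
cohort.write_fasta("families.fasta")
cfg = RunConfig(workflow="cohort", input_path="families.fasta",
                output_dir="out", k_clusters=3)
result = run_cohort_workflow(cfg)
print(result["summary"].to_json())
```

prints

```json
{
  "length_max": 90,
  "length_min": 40,
  "n_top_gated": 4,
  "n_total": 12,
  "percent_top_gated": 33.3
}
```

(histogram omitted here): all 12 sequences were annotated, and exactly
the 4 members of the planted long-region family were classified
top-gated (33.3 %). `out/` additionally holds the cluster table, the
per-sequence annotation TSV, the newick tree and a report restating every
resolved setting.

On the structure side, a generated C15 channel with a planted gate of
7 Å radius, one bridge-compatible residue (5 Å apart between adjacent
subunits) and one negative control (12 Å):

```python
from secgate import (ChannelSpec, crosslink_scan, find_constrictions,
                     gen_cn_channel, pore_profile)

chan = gen_cn_channel(ChannelSpec(n_chains=15, gate_radius=7.0,
                                  planted_pair_positions=[5],
                                  planted_negative_positions=[20], seed=13))
profile = pore_profile(chan.structure)
print(find_constrictions(profile, max_diameter=15.0))
print([(c.resnum, round(c.distance, 2), c.bridge_compatible)
       for c in crosslink_scan(chan.structure) if c.resnum in (5, 20)])
```

prints

```
[(0.0, 10.6)]
[(5, 5.0, True), (20, 12.0, False)]
```

— one constriction of diameter 10.6 Å (the analytic value
2·(7 − 1.7) Å for carbon atoms of 1.7 Å vdW radius), and the planted
positive/negative cross-link verdicts recovered exactly.

A CLI wraps the same workflows: `secgate cohort`, `secgate structure`,
`secgate simulate`, `secgate gc` (see `secgate --help`).

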
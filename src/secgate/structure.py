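"""Gate geometry of Cn-symmetric channel structures.

Secretins are large outer-membrane channels built from 12-15 identical
subunits arranged with Cn rotational symmetry about a central axis. Their
lumen is interrupted by horizontal closures ("gates"): loops from every
subunit converge toward the axis and constrict the pore. This module
quantifies that geometry on PDB/mmCIF coordinates:

* :func:`pore_profile` — accessible radius along the symmetry axis
  (on-axis measurement: distance from the axis to the nearest atom
  surface in each z slab);
* :func:`find_constrictions` — local pore minima below a diameter cutoff;
* :func:`crosslink_scan` — for each residue number, the minimal
  inter-chain Cβ-Cβ distance between equivalent residues, screened
  against a disulfide-engineering distance threshold;
* :func:`detect_hairpin_strands` — Cα-geometric detection of the
  two-stranded antiparallel β-hairpin that forms the apical "top gate".

The on-axis aperture measure is exact for Cn-symmetric channels and fully
deterministic; it does not attempt the off-axis sphere optimisation of
general channel-profiling algorithms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Van der Waals radii (Å) by element; a fixed published element table.
DEFAULT_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
VDW_FALLBACK = 1.70

#: Default Cβ-Cβ distance (Å) considered compatible with engineering an
#: inter-subunit disulfide bridge.
BRIDGE_THRESHOLD = 7.0

ATOM_COLUMNS = ["chain", "resnum", "resname", "atom", "element", "x", "y", "z"]


@dataclass
class ChannelStructure:
    """Atom table of an oligomeric channel plus its symmetry description.

    ``atoms`` columns: chain, resnum (1-based author numbering), resname,
    atom name, element symbol, x/y/z in Å. ``axis`` is an anchored unit
    vector ``(origin, direction)`` once estimated.
    """

    atoms: pd.DataFrame
    symmetry_order: int | None = None
    axis: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self):
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValidationError(f"atom table missing columns: {sorted(missing)}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        if len(xyz) == 0:
            raise ValidationError("structure contains no atoms")
        if not np.all(np.isfinite(xyz)):
            raise ValidationError("non-finite atom coordinates")
        if self.symmetry_order is None:
            self.symmetry_order = self.atoms["chain"].nunique()

    @property
    def chains(self) -> list[str]:
        return sorted(self.atoms["chain"].unique())

    @property
    def n_chains(self) -> int:
        return self.atoms["chain"].nunique()

    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    def to_gemmi(self, name: str = "channel") -> gemmi.Structure:
        st = gemmi.Structure()
        st.name = name
        model = gemmi.Model("1")
        for chain_id, chain_df in self.atoms.groupby("chain", sort=True):
            chain = gemmi.Chain(str(chain_id))
            for resnum, res_df in chain_df.groupby("resnum", sort=True):
                res = gemmi.Residue()
                res.name = str(res_df["resname"].iloc[0])
                res.seqid = gemmi.SeqId(int(resnum), " ")
                for row in res_df.itertuples():
                    atom = gemmi.Atom()
                    atom.name = row.atom
                    atom.element = gemmi.Element(row.element)
                    atom.pos = gemmi.Position(row.x, row.y, row.z)
                    atom.occ = 1.0
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        return st

    def write_pdb(self, path: str | Path) -> None:
        self.to_gemmi().write_pdb(str(path))

    def write_mmcif(self, path: str | Path) -> None:
        self.to_gemmi().make_mmcif_document().write_file(str(path))


def read_structure(path: str | Path, include_hetero: bool = False) -> ChannelStructure:
    """Read a PDB or mmCIF file into a :class:`ChannelStructure`.

    Waters are always dropped; other heteroatoms are dropped unless
    ``include_hetero``. Author residue numbering is preserved. Only the
    first model of multi-model files is read.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValidationError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    st.remove_waters()
    rows = []
    model = st[0]
    for chain in model:
        for res in chain:
            if not include_hetero and res.het_flag == "H":
                continue
            for atom in res:
                rows.append(
                    {
                        "chain": chain.name,
                        "resnum": res.seqid.num,
                        "resname": res.name,
                        "atom": atom.name,
                        "element": atom.element.name,
                        "x": atom.pos.x,
                        "y": atom.pos.y,
                        "z": atom.pos.z,
                    }
                )
    if not rows:
        raise ValidationError(f"no atoms parsed from {path}")
    return ChannelStructure(atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS))


def estimate_axis(structure: ChannelStructure) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the Cn symmetry axis (anchored unit vector).

    Chain centroids of a Cn assembly lie on a ring; the axis is the
    direction of least variance of those centroids (the ring-plane
    normal), anchored at the all-atom centroid. The direction sign is
    fixed by making the largest-magnitude component positive.
    """
    if structure.n_chains < 3:
        raise ValidationError(
            f"axis estimation needs >=3 chains, got {structure.n_chains}"
        )
    centroids = (
        structure.atoms.groupby("chain")[["x", "y", "z"]].mean().to_numpy(float)
    )
    centered = centroids - centroids.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    # Ring geometry: two large in-plane eigenvalues, one near-zero normal.
    # Collinear centroids leave two near-zero eigenvalues: the normal is
    # then ambiguous.
    if evals[1] < 1e-9 * max(evals[2], 1e-12):
        raise ValidationError("degenerate chain geometry: symmetry axis ambiguous")
    direction = evecs[:, 0]
    i = int(np.argmax(np.abs(direction)))
    if direction[i] < 0:
        direction = -direction
    origin = structure.coords().mean(axis=0)
    axis = (origin, direction / np.linalg.norm(direction))
    structure.axis = axis
    return axis


@dataclass
class PoreProfile:
    """Accessible pore radius sampled along the symmetry axis.

    ``z`` is the axial coordinate relative to the axis anchor; the
    accessible radius at each z is the minimum over atoms in the slab
    ``|t - z| <= z_step`` of (axial distance of the atom centre − its vdW
    radius), floored at zero. Slabs containing no atoms hold NaN.
    """

    z: np.ndarray
    radius: np.ndarray
    z_step: float
    vdw_set: str = "default"

    def __post_init__(self):
        if len(self.z) != len(self.radius):
            raise ValidationError("z and radius length mismatch")
        if np.any(np.diff(self.z) <= 0):
            raise ValidationError("z must be strictly increasing")

    @property
    def diameter(self) -> np.ndarray:
        return 2.0 * self.radius

    def min_diameter(self) -> float:
        """Smallest measured pore diameter (Å), ignoring empty slabs."""
        return float(np.nanmin(self.diameter))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z": self.z, "radius": self.radius, "diameter": self.diameter}
        )


def pore_profile(
    structure: ChannelStructure,
    z_step: float = 1.0,
    vdw: dict[str, float] | None = None,
) -> PoreProfile:
    """Profile the accessible pore radius along the symmetry axis."""
    if z_step <= 0:
        raise ValidationError("z_step must be positive")
    if structure.axis is None:
        estimate_axis(structure)
    origin, direction = structure.axis
    table = dict(DEFAULT_VDW if vdw is None else vdw)
    xyz = structure.coords() - origin
    t = xyz @ direction  # axial coordinate
    radial = np.linalg.norm(xyz - np.outer(t, direction), axis=1)
    vdw_r = structure.atoms["element"].map(
        lambda e: table.get(e, VDW_FALLBACK)
    ).to_numpy(float)
    zs = np.arange(math.floor(t.min()), math.ceil(t.max()) + z_step / 2, z_step)
    radius = np.full(len(zs), np.nan)
    for i, z in enumerate(zs):
        mask = np.abs(t - z) <= z_step
        if not mask.any():
            continue
        radius[i] = max(0.0, float(np.min(radial[mask] - vdw_r[mask])))
    return PoreProfile(z=zs, radius=radius, z_step=z_step)


def find_constrictions(
    profile: PoreProfile, max_diameter: float
) -> list[tuple[float, float]]:
    """Local pore-diameter minima below ``max_diameter``.

    Minima closer than 3 Å along z are merged (the tightest one is kept).
    Returns ``(z, diameter)`` pairs sorted by z.
    """
    d = profile.diameter
    filled = np.where(np.isnan(d), np.inf, d)
    # interior local minima only: the boundary minimum of a monotone
    # profile is not a constriction
    candidates = [
        (float(profile.z[i]), float(d[i]))
        for i in range(1, len(d) - 1)
        if not np.isnan(d[i])
        and d[i] < max_diameter
        and filled[i] <= filled[i - 1]
        and filled[i] <= filled[i + 1]
    ]
    kept: list[tuple[float, float]] = []
    for z, diam in sorted(candidates, key=lambda c: (c[1], c[0])):
        if all(abs(z - zk) > 3.0 for zk, _ in kept):
            kept.append((z, diam))
    return sorted(kept)


@dataclass(frozen=True)
class CrosslinkCandidate:
    """Inter-subunit cross-link screen result for one residue number."""

    resnum: int
    chain_pair: tuple[str, str]
    distance: float
    bridge_compatible: bool
    threshold: float


def _reference_atoms(structure: ChannelStructure) -> pd.DataFrame:
    """One reference atom per (chain, resnum): Cβ, or Cα for glycine /
    residues lacking a Cβ."""
    atoms = structure.atoms
    cb = atoms[atoms["atom"] == "CB"]
    ca = atoms[atoms["atom"] == "CA"]
    have_cb = set(zip(cb["chain"], cb["resnum"]))
    fallback = ca[~ca.apply(lambda r: (r["chain"], r["resnum"]) in have_cb, axis=1)]
    ref = pd.concat([cb, fallback], ignore_index=True)
    return ref.drop_duplicates(subset=["chain", "resnum"], keep="first")


def _angular_chain_order(structure: ChannelStructure) -> list[str]:
    """Chains sorted by angular position about the symmetry axis."""
    if structure.axis is None:
        estimate_axis(structure)
    origin, direction = structure.axis
    # Build an orthonormal frame (u, v, direction).
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - (ref @ direction) * direction
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    order = []
    for chain, df in structure.atoms.groupby("chain"):
        c = df[["x", "y", "z"]].mean().to_numpy(float) - origin
        order.append((math.atan2(c @ v, c @ u), chain))
    return [c for _, c in sorted(order)]


def crosslink_scan(
    structure: ChannelStructure,
    threshold: float = BRIDGE_THRESHOLD,
    mode: str = "adjacent",
) -> list[CrosslinkCandidate]:
    """Screen every residue number for inter-subunit disulfide compatibility.

    For each residue number shared by all chains, computes the minimal
    distance between reference atoms (Cβ; Cα for glycine) of the *same*
    residue number in two different chains. ``mode="adjacent"`` restricts
    chain pairs to angular neighbours about the axis; ``mode="all-pairs"``
    considers every chain pair. The verdict is
    ``distance <= threshold``.

    Residue numbers missing from some chains are skipped with a warning.
    """
    if mode not in ("adjacent", "all-pairs"):
        raise ValidationError(f"unknown mode {mode!r}")
    if structure.n_chains < 2:
        raise ValidationError("crosslink scan needs an oligomer (>=2 chains)")
    ref = _reference_atoms(structure)
    chains = _angular_chain_order(structure)
    n = len(chains)
    if mode == "adjacent":
        pairs = [(chains[i], chains[(i + 1) % n]) for i in range(n)]
    else:
        pairs = list(combinations(chains, 2))
    coords: dict[str, dict[int, np.ndarray]] = {
        chain: {
            int(r.resnum): np.array([r.x, r.y, r.z]) for r in df.itertuples()
        }
        for chain, df in ref.groupby("chain")
    }
    all_resnums = sorted(set().union(*(set(m) for m in coords.values())))
    common = [rn for rn in all_resnums if all(rn in coords[c] for c in chains)]
    skipped = set(all_resnums) - set(common)
    if skipped:
        logger.warning(
            "residues %s missing from some chains; skipped", sorted(skipped)
        )
    out = []
    for rn in common:
        best, best_pair = math.inf, None
        for ca_, cb_ in pairs:
            dist = float(np.linalg.norm(coords[ca_][rn] - coords[cb_][rn]))
            if dist < best:
                best, best_pair = dist, tuple(sorted((ca_, cb_)))
        out.append(
            CrosslinkCandidate(
                resnum=rn,
                chain_pair=best_pair,
                distance=best,
                bridge_compatible=best <= threshold,
                threshold=threshold,
            )
        )
    return out


def crosslinks_to_frame(candidates: list[CrosslinkCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "resnum": c.resnum,
                "chain_a": c.chain_pair[0],
                "chain_b": c.chain_pair[1],
                "distance": c.distance,
                "bridge_compatible": c.bridge_compatible,
                "threshold": c.threshold,
            }
            for c in candidates
        ]
    )


@dataclass
class StrandPairCall:
    """Verdict on the presence of a two-stranded antiparallel hairpin."""

    window: tuple[int, int]
    detected: bool
    strand_segments: list[tuple[int, int]] = field(default_factory=list)
    paired_registers: list[tuple[int, int]] = field(default_factory=list)


def detect_hairpin_strands(
    structure: ChannelStructure,
    window: tuple[int, int],
    chain: str | None = None,
    extended_min_i3: float = 7.0,
    cross_range: tuple[float, float] = (4.5, 6.0),
) -> StrandPairCall:
    """Detect the top-gate β-hairpin in a monomer model by Cα geometry.

    A residue run is called a strand segment when consecutive Cα-Cα
    spacings are peptide-like (2.8-4.3 Å) and the chain is extended
    (Cα(i)-Cα(i+3) distance above ``extended_min_i3``; β strands run
    near 10 Å, α helices near 5 Å). The hairpin is detected when two
    disjoint segments of >=3 residues in the window show an antiparallel
    register: >=2 consecutive residues of one strand pairing at
    cross-strand Cα distances within ``cross_range`` to residues of the
    other strand with *decreasing* partner index.

    No hydrogen-bond term is used, so the detector works on Cα-only
    models.
    """
    lo, hi = window
    if lo > hi:
        raise ValidationError("window start must not exceed end")
    atoms = structure.atoms
    if chain is None:
        chain = sorted(atoms["chain"].unique())[0]
    ca = atoms[(atoms["chain"] == chain) & (atoms["atom"] == "CA")]
    chain_min, chain_max = int(ca["resnum"].min()), int(ca["resnum"].max())
    if lo < chain_min or hi > chain_max:
        raise ValidationError(
            f"window {window} outside chain {chain} range [{chain_min},{chain_max}]"
        )
    ca = ca[(ca["resnum"] >= lo) & (ca["resnum"] <= hi)].sort_values("resnum")
    resnums = ca["resnum"].to_numpy(int)
    xyz = ca[["x", "y", "z"]].to_numpy(float)

    n = len(resnums)
    extended = np.zeros(n, bool)
    for i in range(n - 3):
        if resnums[i + 3] - resnums[i] != 3:
            continue
        spacings_ok = all(
            2.8 <= np.linalg.norm(xyz[j + 1] - xyz[j]) <= 4.3 for j in range(i, i + 3)
        )
        if spacings_ok and np.linalg.norm(xyz[i + 3] - xyz[i]) >= extended_min_i3:
            extended[i : i + 4] = True

    segments: list[tuple[int, int]] = []  # index ranges [a, b] inclusive
    i = 0
    while i < n:
        if extended[i]:
            j = i
            while j + 1 < n and extended[j + 1] and resnums[j + 1] - resnums[j] == 1:
                j += 1
            if j - i + 1 >= 3:
                segments.append((i, j))
            i = j + 1
        else:
            i += 1

    call = StrandPairCall(
        window=window,
        detected=False,
        strand_segments=[(int(resnums[a]), int(resnums[b])) for a, b in segments],
    )
    cr_lo, cr_hi = cross_range
    for (a0, a1), (b0, b1) in combinations(segments, 2):
        # Partner of each residue in segment A: nearest residue of B at
        # cross-strand distance.
        partners = {}
        for i in range(a0, a1 + 1):
            dists = [np.linalg.norm(xyz[i] - xyz[j]) for j in range(b0, b1 + 1)]
            jmin = int(np.argmin(dists))
            if cr_lo <= dists[jmin] <= cr_hi:
                partners[i] = b0 + jmin
        run = [
            i
            for i in range(a0, a1)
            if i in partners and i + 1 in partners and partners[i + 1] < partners[i]
        ]
        if run:
            i = run[0]
            call.detected = True
            call.paired_registers = [
                (int(resnums[i]), int(resnums[partners[i]])),
                (int(resnums[i + 1]), int(resnums[partners[i + 1]])),
            ]
            break
    return call
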
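"""End-to-end workflows: sequence cohort analysis and structure gate analysis.

Each workflow reads its inputs, runs the corresponding module chain and
writes a report bundle into an output directory. Runs are deterministic
for a fixed configuration and seed, and every bundle contains a
``report.txt`` restating the fully resolved configuration so any number
in any output can be regenerated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import apical, clustering, genome, structure
from .errors import StageError, ValidationError
from .records import read_fasta

logger = logging.getLogger("secgate")


@dataclass
class RunConfig:
    """Resolved configuration of one workflow run.

    Flags default to the documented module defaults; a flat TOML config
    file may override them and CLI flags override the file.
    """

    workflow: str = ""
    input_path: str = ""
    output_dir: str = "secgate_out"
    seed: int = 0
    # apical annotation
    left_motif: str = apical.LEFT_MOTIF
    right_motif: str = apical.RIGHT_MOTIF
    threshold: int = apical.TOP_GATE_THRESHOLD
    # clustering
    identity_min: float = clustering.IDENTITY_MIN
    coverage_min: float = clustering.COVERAGE_MIN
    k_clusters: int = 10
    # structure gates
    crosslink_threshold: float = structure.BRIDGE_THRESHOLD
    crosslink_mode: str = "adjacent"
    z_step: float = 1.0
    max_diameter: float = 15.0
    window: tuple[int, int] | None = None
    # genome context
    gc_tolerance: float = genome.GC_TOLERANCE

    def validate(self) -> None:
        if self.input_path and not Path(self.input_path).exists():
            raise ValidationError(f"input path does not exist: {self.input_path}")
        if not 0.0 <= self.identity_min <= 1.0 or not 0.0 <= self.coverage_min <= 1.0:
            raise ValidationError("identity/coverage thresholds must be in [0, 1]")
        if self.threshold < 0 or self.k_clusters < 1:
            raise ValidationError("threshold must be >= 0 and k_clusters >= 1")
        if self.z_step <= 0 or self.crosslink_threshold <= 0:
            raise ValidationError("z_step and crosslink_threshold must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(data.get("window"), list):
            data["window"] = tuple(data["window"])
        return cls(**data)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window) if self.window else None
        return d


def _report(config: RunConfig, outdir: Path, stages: list[tuple[str, float]]) -> None:
    lines = ["secgate run report", "=" * 60, "", "resolved configuration:"]
    for k, v in sorted(config.resolved().items()):
        lines.append(f"  {k} = {v!r}")
    lines += ["", "stages (seconds):"]
    lines += [f"  {name}: {dt:.3f}" for name, dt in stages]
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


def _timed(stages: list, name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except ValidationError:
        raise
    except Exception as exc:
        raise StageError(name, str(exc)) from exc
    stages.append((name, time.perf_counter() - t0))
    logger.info("stage %s finished in %.3f s", name, stages[-1][1])
    return result


def run_cohort_workflow(config: RunConfig) -> dict:
    """Cluster a protein cohort, annotate apical regions, summarise and
    build the representative tree.

    Order: greedy clustering -> top-k selection -> apical annotation of
    the selected clusters' members -> cohort summary -> NJ tree over the
    selected centroids (skipped with a warning below 3 centroids).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[tuple[str, float]] = []

    records = _timed(stages, "read_fasta", read_fasta, config.input_path)
    clusters = _timed(
        stages, "greedy_cluster", clustering.greedy_cluster,
        records, config.identity_min, config.coverage_min,
    )
    top = _timed(
        stages, "select_top_clusters", clustering.select_top_clusters,
        clusters, config.k_clusters,
    )
    clustering.clusters_to_frame(top, records).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False, float_format="%.6f"
    )
    by_id = {r.id: r for r in records}
    selected = [by_id[m] for c in top for m in c.member_ids]

    def annotate():
        return apical.annotate_cohort(
            selected,
            threshold=config.threshold,
            left_motif=config.left_motif,
            right_motif=config.right_motif,
        )

    annotations = _timed(stages, "apical_annotation", annotate)
    apical.annotations_to_frame(annotations).to_csv(
        outdir / "annotations.tsv", sep="\t", index=False, float_format="%.6f"
    )
    summary = _timed(stages, "summarize", apical.summarize_cohort, annotations)
    summary.to_json(outdir / "summary.json")

    centroids = [by_id[c.centroid_id] for c in top]
    tree = None
    if len(centroids) >= 3:
        tree = _timed(stages, "nj_tree", clustering.nj_tree, centroids)
        clustering.write_newick(tree, outdir / "tree.nwk")
    else:
        logger.warning("fewer than 3 cluster representatives; tree skipped")
    _report(config, outdir, stages)
    return {
        "clusters": clusters,
        "top_clusters": top,
        "annotations": annotations,
        "summary": summary,
        "tree": tree,
        "output_dir": outdir,
    }


def run_structure_workflow(config: RunConfig) -> dict:
    """Profile the pore, find constrictions and scan cross-link sites of a
    channel structure; optionally call the top-gate hairpin in a window.

    Oligomer analyses require >= 3 chains; on monomer input only the
    strand call is produced (with a warning).
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[tuple[str, float]] = []

    cs = _timed(stages, "read_structure", structure.read_structure, config.input_path)
    result: dict = {"structure": cs, "output_dir": outdir}
    if cs.n_chains >= 3:
        _timed(stages, "estimate_axis", structure.estimate_axis, cs)
        profile = _timed(stages, "pore_profile", structure.pore_profile, cs,
                         config.z_step)
        profile.to_frame().to_csv(
            outdir / "pore_profile.tsv", sep="\t", index=False, float_format="%.4f"
        )
        constrictions = _timed(
            stages, "find_constrictions", structure.find_constrictions,
            profile, config.max_diameter,
        )
        (outdir / "constrictions.json").write_text(
            json.dumps(
                {
                    "max_diameter": config.max_diameter,
                    "constrictions": [
                        {"z": z, "diameter": d} for z, d in constrictions
                    ],
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        candidates = _timed(
            stages, "crosslink_scan", structure.crosslink_scan,
            cs, config.crosslink_threshold, config.crosslink_mode,
        )
        frame = structure.crosslinks_to_frame(candidates).sort_values(
            ["distance", "resnum"]
        )
        frame.to_csv(
            outdir / "crosslinks.tsv", sep="\t", index=False, float_format="%.4f"
        )
        result.update(
            profile=profile, constrictions=constrictions, crosslinks=candidates
        )
    else:
        logger.warning(
            "structure has %d chain(s); oligomer analyses skipped", cs.n_chains
        )
    if config.window is not None:
        call = _timed(
            stages, "detect_hairpin", structure.detect_hairpin_strands,
            cs, config.window,
        )
        (outdir / "strand_call.json").write_text(
            json.dumps(
                {
                    "window": list(call.window),
                    "detected": call.detected,
                    "strand_segments": [list(s) for s in call.strand_segments],
                    "paired_registers": [list(p) for p in call.paired_registers],
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        result["strand_call"] = call
    _report(config, outdir, stages)
    return result


def setup_logging(verbose: bool = False) -> None:
    """Log to stderr only; results never go to stderr streams."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
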
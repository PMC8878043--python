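"""End-to-end orchestration: annotate -> nucleotide similarity -> protein
groups -> taxonomy -> pangenome -> network export, with a JSON run manifest
recording the config, input checksums, per-stage wall time and output
checksums.  Identical config + inputs give byte-identical non-log outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .genome_io import (
    GenomeRecord,
    all_proteins,
    ensure_annotated,
    read_genomes,
    write_manifest,
)
from .network_export import (
    content_distance,
    presence_absence,
    write_heatmap_table,
    write_nexus_distances,
)
from .nt_similarity import ScoringParams, similarity_matrix, write_similarity_matrix
from .protein_clustering import build_groups, shared_content, write_groups_table
from .taxonomy import (
    classify,
    dendrogram_leaf_order,
    summarise_pangenome,
    write_taxonomy_report,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults are the standard demarcations
    (species 95, genus 65, cluster 30, protein identity 0.35 / coverage 0.5,
    minimum ORF 120 nt)."""

    input_paths: list[str] = field(default_factory=list)
    out_dir: str = "phagetax_out"
    input_format: str | None = None
    species_threshold: float = 95.0
    genus_threshold: float = 65.0
    cluster_threshold: float = 30.0
    protein_identity: float = 0.35
    protein_coverage: float = 0.50
    min_orf_nt: int = 120
    backend: str = "internal"
    seed: int = 0
    schema_version: int = 1

    def validate(self) -> None:
        if not 0 < self.genus_threshold <= self.species_threshold <= 100:
            raise ValueError("need 0 < genus_threshold <= species_threshold <= 100")
        if not 0 < self.cluster_threshold < 100:
            raise ValueError("cluster_threshold must be in (0, 100)")
        if not 0 < self.protein_identity <= 1 or not 0 < self.protein_coverage <= 1:
            raise ValueError("protein thresholds must be in (0, 1]")
        if self.min_orf_nt < 6:
            raise ValueError("min_orf_nt too small")
        if self.backend not in ("internal", "blastn"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _StageRunner:
    def __init__(self, out: Path, manifest: dict):
        self.out = out
        self.manifest = manifest

    def run(self, name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            (self.out / f"{name}.failed").write_text(f"{type(exc).__name__}: {exc}\n")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        self.manifest["stages"].append(
            {"name": name, "seconds": round(time.perf_counter() - t0, 3)}
        )
        logger.info("stage %s done", name)
        return result


def run_all(
    config: RunConfig,
    genomes: Sequence[GenomeRecord] | None = None,
) -> dict:
    """Run every stage and write all artifacts under ``config.out_dir``.

    ``genomes`` may be passed directly (e.g. fresh from the simulator);
    otherwise they are read from ``config.input_paths``.  Returns the run
    manifest (also written as ``manifest.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "phagetax_version": __version__,
        "config": asdict(config),
        "inputs": {},
        "stages": [],
        "outputs": {},
    }
    stage = _StageRunner(out, manifest)

    if genomes is None:
        for p in config.input_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
            manifest["inputs"][p] = _sha256(Path(p))
        genomes = stage.run(
            "read_genomes",
            lambda: read_genomes(config.input_paths, config.input_format),
        )

    genomes = stage.run(
        "annotate", lambda: ensure_annotated(genomes, config.min_orf_nt)
    )
    write_manifest(genomes, out / "genomes.tsv")

    sim = stage.run(
        "nt_similarity",
        lambda: similarity_matrix(genomes, ScoringParams(), config.backend),
    )
    write_similarity_matrix(sim, out / "similarity.tsv")

    proteins = all_proteins(genomes)
    groups = stage.run(
        "protein_groups",
        lambda: build_groups(
            proteins, config.protein_identity, config.protein_coverage
        ),
    )
    write_groups_table(groups, proteins, out / "groups.tsv")

    shared = stage.run("shared_content", lambda: shared_content(genomes, groups))
    shared.to_csv(out / "shared_content.tsv", sep="\t", float_format="%.1f")

    assignments, clusters, lnk = stage.run(
        "taxonomy",
        lambda: classify(
            sim,
            shared,
            config.genus_threshold,
            config.species_threshold,
            config.cluster_threshold,
        ),
    )
    protein_genomes = {p.protein_id: p.genome_id for p in proteins}
    partial = frozenset(g.genome_id for g in genomes if g.partial)
    summaries = stage.run(
        "pangenome",
        lambda: summarise_pangenome(assignments, groups, protein_genomes, partial),
    )
    write_taxonomy_report(
        assignments, summaries, out / "taxonomy.tsv", out / "pangenome.tsv"
    )

    def _network():
        pa = presence_absence(genomes, groups)
        dist = content_distance(pa)
        write_nexus_distances(dist, out / "content_distance.nex")
        order = dendrogram_leaf_order(lnk, list(shared.index))
        cluster_of = {a.genome_id: a.cluster_id for a in assignments}
        write_heatmap_table(shared, order, cluster_of, out / "heatmap.tsv")
        pa.astype(int).to_csv(out / "presence_absence.tsv", sep="\t")

    stage.run("network_export", _network)

    for f in sorted(out.iterdir()):
        if f.name not in ("manifest.json", "run.log") and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
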
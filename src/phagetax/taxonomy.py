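"""Two-tier taxonomy assignment and pangenome partitioning.

Sub-clusters (genera) are connected components of the genome graph with
edges wherever intergenomic nucleotide similarity >= 65%; species are
components at >= 95% within each sub-cluster.  Clusters (subfamilies) come
from a complete-linkage dendrogram on distance = 100 - shared-protein
percent, cut at 70 (i.e. a minimum of 30% shared proteins), with sub-cluster
atomicity enforced: if the cut splits a sub-cluster, the offending clusters
are merged and a warning logged.  A genome is a singleton when it is alone
in its sub-cluster and joins no cluster.

Within each cluster, protein groups are partitioned into core (present in
every member), accessory (in two or more, but not all) and unique (in a
single member); for single-genome clusters core/accessory are undefined
(reported as N/A) and proteins split into unique vs shared with the rest of
the dataset.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .protein_clustering import ProteinGroup

logger = logging.getLogger(__name__)

SINGLETON = "SINGLETON"


@dataclass
class TaxonAssignment:
    genome_id: str
    species_id: str
    subcluster_id: str
    cluster_id: str
    label: str
    singleton: bool


@dataclass
class PangenomeSummary:
    """Per-cluster core/accessory/unique accounting (None = N/A)."""

    cluster_id: str
    n_genomes: int
    n_core: int | None
    n_accessory: int | None
    n_unique: int
    n_core_exclusive: int | None
    n_shared: int | None = None  # single-genome clusters only


def _check_similarity_matrix(sim: pd.DataFrame) -> None:
    if not np.allclose(sim.values, sim.values.T, atol=1e-9):
        raise ValueError("similarity matrix is not symmetric")
    if list(sim.index) != list(sim.columns):
        raise ValueError("matrix row/column labels disagree")


def _components(
    sim: pd.DataFrame, ids: Sequence[str], threshold: float
) -> list[list[str]]:
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    sub = sim.loc[list(ids), list(ids)]
    arr = sub.values
    for i, j in zip(*np.nonzero(np.triu(arr >= threshold, k=1))):
        graph.add_edge(ids[i], ids[j])
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def assign_subclusters(
    sim: pd.DataFrame,
    genus_threshold: float = 65.0,
    species_threshold: float = 95.0,
) -> tuple[list[list[str]], list[list[str]]]:
    """Nested genus/species partitions from the similarity matrix.

    Returns ``(subclusters, species)`` as lists of sorted genome_id lists;
    sub-clusters ordered by size (desc) then smallest member, species grouped
    within each sub-cluster.  Species are nested within sub-clusters by
    construction.
    """
    _check_similarity_matrix(sim)
    ids = list(sim.index)
    subclusters = _components(sim, ids, genus_threshold)
    species: list[list[str]] = []
    for sc in subclusters:
        species.extend(_components(sim, sc, species_threshold))
    return subclusters, species


def assign_clusters(
    shared: pd.DataFrame,
    subclusters: Sequence[Sequence[str]],
    cluster_threshold: float = 30.0,
) -> tuple[list[list[str]], np.ndarray]:
    """Cluster (subfamily) partition from shared-protein content.

    Complete-linkage hierarchical clustering on distance = 100 - shared%,
    cut at 100 - ``cluster_threshold``; sub-clusters are kept atomic by
    merging any clusters that the cut would split them across.  Returns the
    clusters (sorted genome_id lists, size desc then smallest member) and
    the scipy linkage matrix.
    """
    _check_similarity_matrix(shared)
    ids = list(shared.index)
    in_subclusters = sorted(g for sc in subclusters for g in sc)
    if in_subclusters != sorted(ids):
        raise ValueError("sub-cluster partition does not cover the matrix genomes")
    dist = 100.0 - shared.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    if len(ids) < 2:
        return [list(ids)], np.empty((0, 4))
    lnk = linkage(squareform(dist, checks=False), method="complete")
    flat = fcluster(lnk, t=100.0 - cluster_threshold, criterion="distance")
    assignment = dict(zip(ids, flat))
    # enforce sub-cluster atomicity: merge clusters split by the cut
    merged = nx.utils.UnionFind(sorted(set(flat)))
    for sc in subclusters:
        labels = {assignment[g] for g in sc}
        if len(labels) > 1:
            logger.warning(
                "cluster cut split sub-cluster %s across %d branches; merging",
                sc[0],
                len(labels),
            )
            first, *rest = sorted(labels)
            for lab in rest:
                merged.union(first, lab)
    by_root: dict[int, list[str]] = {}
    for g in ids:
        by_root.setdefault(merged[assignment[g]], []).append(g)
    clusters = [sorted(c) for c in by_root.values()]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters, lnk


def _letters() -> Iterable[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for size in itertools.count(1):
        for combo in itertools.product(alphabet, repeat=size):
            yield "".join(combo)


def make_assignments(
    subclusters: Sequence[Sequence[str]],
    species: Sequence[Sequence[str]],
    clusters: Sequence[Sequence[str]],
) -> list[TaxonAssignment]:
    """Deterministic labels: cluster letters by size desc then smallest
    member; sub-cluster numbers within each cluster likewise (e.g. "A1").

    Single-genome clusters whose sub-cluster is also a singleton are flagged
    SINGLETON and labelled SGL1, SGL2, ... by genome_id order.
    """
    subcluster_of = {g: i for i, sc in enumerate(subclusters) for g in sc}
    species_of = {g: i for i, sp in enumerate(species) for g in sp}
    # species are emitted per sub-cluster in deterministic order; rank them
    # within their sub-cluster for labelling
    species_rank: dict[int, int] = {}
    counter: dict[int, int] = {}
    for i, sp in enumerate(species):
        sc = subcluster_of[sp[0]]
        counter[sc] = counter.get(sc, 0) + 1
        species_rank[i] = counter[sc]
    real = [c for c in clusters if len(c) > 1]
    singles = sorted(c[0] for c in clusters if len(c) == 1)
    cluster_letter: dict[int, str] = {}
    assignments: dict[str, TaxonAssignment] = {}
    letters = _letters()
    for ci, members in enumerate(real):
        letter = next(letters)
        scs = sorted(
            {subcluster_of[g] for g in members},
            key=lambda s: (-len(subclusters[s]), subclusters[s][0]),
        )
        sc_number = {s: k + 1 for k, s in enumerate(scs)}
        for g in sorted(members):
            label = f"{letter}{sc_number[subcluster_of[g]]}"
            assignments[g] = TaxonAssignment(
                genome_id=g,
                species_id=f"{label}.s{species_rank[species_of[g]]}",
                subcluster_id=label,
                cluster_id=letter,
                label=label,
                singleton=False,
            )
    for k, g in enumerate(singles, start=1):
        label = f"SGL{k}"
        assignments[g] = TaxonAssignment(
            genome_id=g,
            species_id=f"{label}.s1",
            subcluster_id=label,
            cluster_id=SINGLETON,
            label=label,
            singleton=True,
        )
    return [assignments[g] for g in sorted(assignments)]


def classify(
    sim: pd.DataFrame,
    shared: pd.DataFrame,
    genus_threshold: float = 65.0,
    species_threshold: float = 95.0,
    cluster_threshold: float = 30.0,
) -> tuple[list[TaxonAssignment], list[list[str]], np.ndarray]:
    """Full two-tier classification; returns assignments, clusters, linkage."""
    subclusters, species = assign_subclusters(sim, genus_threshold, species_threshold)
    clusters, lnk = assign_clusters(shared, subclusters, cluster_threshold)
    return make_assignments(subclusters, species, clusters), clusters, lnk


def pangenome_partition(
    cluster_id: str,
    members: Sequence[str],
    groups: Sequence[ProteinGroup],
    protein_genomes: Mapping[str, str],
    partial: frozenset[str] | set[str] = frozenset(),
) -> PangenomeSummary:
    """Partition the cluster's protein groups into core/accessory/unique.

    ``protein_genomes`` maps protein_id -> genome_id.  Genomes in ``partial``
    are excluded from the core denominator but their groups still count.
    Every group with at least one member in the cluster is classified exactly
    once; unique is counted in proteins, core/accessory in groups.
    """
    if not members:
        raise ValueError("empty cluster")
    member_set = set(members)
    core_universe = sorted(member_set - set(partial)) or sorted(member_set)
    n_core = n_acc = n_unique = n_core_excl = 0
    n_shared_elsewhere = 0
    for grp in groups:
        in_cluster = [m for m in grp.members if protein_genomes[m] in member_set]
        if not in_cluster:
            continue
        present = {protein_genomes[m] for m in in_cluster}
        if len(present) == 1:
            if grp.genomes <= member_set:
                n_unique += len(in_cluster)
            else:
                n_shared_elsewhere += len(in_cluster)
        elif set(core_universe) <= present:
            n_core += 1
            if not grp.genomes - member_set:
                n_core_excl += 1
        else:
            n_acc += 1
    if len(member_set) == 1:
        return PangenomeSummary(
            cluster_id=cluster_id,
            n_genomes=1,
            n_core=None,
            n_accessory=None,
            n_unique=n_unique,
            n_core_exclusive=None,
            n_shared=n_shared_elsewhere,
        )
    return PangenomeSummary(
        cluster_id=cluster_id,
        n_genomes=len(member_set),
        n_core=n_core,
        n_accessory=n_acc,
        n_unique=n_unique + n_shared_elsewhere,
        n_core_exclusive=n_core_excl,
    )


def summarise_pangenome(
    assignments: Sequence[TaxonAssignment],
    groups: Sequence[ProteinGroup],
    protein_genomes: Mapping[str, str],
    partial: frozenset[str] | set[str] = frozenset(),
) -> list[PangenomeSummary]:
    """One summary per cluster (letters first, then singletons)."""
    by_cluster: dict[str, list[str]] = {}
    for a in assignments:
        key = a.cluster_id if not a.singleton else a.label
        by_cluster.setdefault(key, []).append(a.genome_id)
    out = []
    for cid in sorted(by_cluster, key=lambda c: (c.startswith("SGL"), len(c), c)):
        out.append(
            pangenome_partition(
                cid, by_cluster[cid], groups, protein_genomes, partial
            )
        )
    return out


def _fmt(v: int | None) -> str:
    return "N/A" if v is None else str(v)


def write_taxonomy_report(
    assignments: Sequence[TaxonAssignment],
    summaries: Sequence[PangenomeSummary],
    assignments_path,
    summary_path,
) -> None:
    """Per-genome assignment TSV + per-cluster summary TSV (deterministic)."""
    with open(assignments_path, "w") as fh:
        fh.write("genome_id\tspecies_id\tsubcluster_id\tcluster_id\tlabel\tsingleton\n")
        for a in sorted(assignments, key=lambda a: a.genome_id):
            fh.write(
                f"{a.genome_id}\t{a.species_id}\t{a.subcluster_id}\t"
                f"{a.cluster_id}\t{a.label}\t{int(a.singleton)}\n"
            )
    with open(summary_path, "w") as fh:
        fh.write(
            "cluster_id\tn_genomes\tn_core\tn_accessory\tn_unique\t"
            "n_core_exclusive\tn_shared\n"
        )
        for s in summaries:
            fh.write(
                f"{s.cluster_id}\t{s.n_genomes}\t{_fmt(s.n_core)}\t"
                f"{_fmt(s.n_accessory)}\t{s.n_unique}\t"
                f"{_fmt(s.n_core_exclusive)}\t{_fmt(s.n_shared)}\n"
            )


def dendrogram_leaf_order(lnk: np.ndarray, ids: Sequence[str]) -> list[str]:
    if lnk.size == 0:
        return list(ids)
    return [ids[i] for i in leaves_list(lnk)]
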
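"""Orthologous protein grouping (phams) and shared-protein-content matrix.

Proteins are compared by local alignment (BLOSUM62, gap open 11 / extend 1);
a pair matches when alignment identity >= ``min_identity`` (default 0.35,
the midpoint of the 30-40% range used for phage pangenomes) and the aligned
span covers >= ``min_coverage`` (default 0.50) of BOTH sequences.  Groups
are connected components of the resulting match graph (single linkage), so
they partition the proteome; a group with a single member is an "orpham".

The genome-level summary is the symmetric shared-content percentage

    shared%(a, b) = 100 * (s_a + s_b) / (n_a + n_b)

where ``s_a`` counts a's proteins whose group also contains a protein of b.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import CDSRecord, GenomeRecord

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM_ALPHABET = set(_BLOSUM62.alphabet)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


_ALIGNER = _make_aligner()


def _sanitise(aa: str) -> str:
    """Map residues outside the substitution-matrix alphabet to X."""
    if set(aa) <= _BLOSUM_ALPHABET:
        return aa
    return "".join(c if c in _BLOSUM_ALPHABET else "X" for c in aa)


class PairMatch(NamedTuple):
    is_match: bool
    identity: float
    coverage: float


def protein_pair_match(
    p: str,
    q: str,
    min_identity: float = 0.35,
    min_coverage: float = 0.50,
) -> PairMatch:
    """Best local alignment of two protein sequences and the match verdict.

    identity = identical residues / alignment columns (gap columns count);
    coverage = aligned span / sequence length, taken as the minimum over the
    two sequences.  Symmetric in its arguments.
    """
    if not p or not q:
        raise ValueError("empty protein sequence")
    p, q = _sanitise(p), _sanitise(q)
    alns = _ALIGNER.align(p, q)
    if len(alns) == 0 or alns.score <= 0:
        return PairMatch(False, 0.0, 0.0)
    aln = alns[0]
    blocks_p, blocks_q = aln.aligned
    identical = 0
    block_cols = 0
    for (ps, pe), (qs, qe) in zip(blocks_p, blocks_q):
        block_cols += pe - ps
        identical += sum(1 for a, b in zip(p[ps:pe], q[qs:qe]) if a == b)
    gap_cols = 0
    for i in range(1, len(blocks_p)):
        gap_cols += blocks_p[i][0] - blocks_p[i - 1][1]
        gap_cols += blocks_q[i][0] - blocks_q[i - 1][1]
    columns = block_cols + gap_cols
    identity = identical / columns if columns else 0.0
    span_p = blocks_p[-1][1] - blocks_p[0][0]
    span_q = blocks_q[-1][1] - blocks_q[0][0]
    coverage = min(span_p / len(p), span_q / len(q))
    return PairMatch(
        identity >= min_identity and coverage >= min_coverage, identity, coverage
    )


@dataclass
class ProteinGroup:
    """An orthologous protein family; orpham when it has a single member."""

    group_id: str
    members: frozenset[str]
    genomes: frozenset[str]

    @property
    def is_orpham(self) -> bool:
        return len(self.members) == 1


def build_groups(
    proteins: Sequence[CDSRecord],
    min_identity: float = 0.35,
    min_coverage: float = 0.50,
    length_prefilter: bool = True,
) -> list[ProteinGroup]:
    """Cluster proteins into groups by single-linkage on pairwise matches.

    Deterministic: group_ids are assigned by the lexicographically smallest
    member protein_id.  Two safe shortcuts keep the all-vs-all affordable:
    identical sequences are aligned once, and pairs already connected through
    earlier matches are not re-aligned (redundant edges cannot change
    connected components).  ``length_prefilter`` skips pairs whose lengths
    differ by more than 4x: the aligned span on the longer sequence is at
    most the full shorter sequence, so coverage < 0.25 < 0.5 and the pair can
    never match.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    ids = [p.protein_id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("protein_ids are not unique")
    order = sorted(range(len(proteins)), key=lambda i: ids[i])
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(ids)

    # collapse identical sequences: one representative per distinct sequence
    by_seq: dict[str, list[int]] = {}
    for i in order:
        by_seq.setdefault(proteins[i].aa_sequence, []).append(i)
    reps = [idxs[0] for idxs in by_seq.values()]
    for idxs in by_seq.values():
        for a, b in zip(idxs, idxs[1:]):
            graph.add_edge(ids[a], ids[b])

    uf = nx.utils.UnionFind(ids)
    for e in graph.edges:
        uf.union(*e)
    for ii in range(len(reps)):
        i = reps[ii]
        pi = proteins[i].aa_sequence
        for jj in range(ii + 1, len(reps)):
            j = reps[jj]
            if uf[ids[i]] == uf[ids[j]]:
                continue
            qj = proteins[j].aa_sequence
            if length_prefilter:
                lmin, lmax = sorted((len(pi), len(qj)))
                if lmax > 4 * lmin:
                    continue
            if protein_pair_match(pi, qj, min_identity, min_coverage).is_match:
                graph.add_edge(ids[i], ids[j])
                uf.union(ids[i], ids[j])

    genome_of = {p.protein_id: p.genome_id for p in proteins}
    groups = []
    for comp in nx.connected_components(graph):
        members = frozenset(comp)
        groups.append(
            ProteinGroup(
                group_id="",
                members=members,
                genomes=frozenset(genome_of[m] for m in members),
            )
        )
    groups.sort(key=lambda g: min(g.members))
    return [
        ProteinGroup(f"pham_{k + 1:05d}", g.members, g.genomes)
        for k, g in enumerate(groups)
    ]


def shared_content(
    genomes: Sequence[GenomeRecord],
    groups: Sequence[ProteinGroup],
) -> pd.DataFrame:
    """Symmetric shared-protein-content percentage matrix (diagonal 100)."""
    group_of: dict[str, ProteinGroup] = {}
    for g in groups:
        for m in g.members:
            group_of[m] = g
    ids = [g.genome_id for g in genomes]
    n_prot = {}
    for g in genomes:
        if not g.cds:
            raise ValueError(f"genome {g.genome_id} has no proteins")
        n_prot[g.genome_id] = len(g.cds)
    n = len(ids)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = genomes[i], genomes[j]
            s_a = sum(
                1 for c in a.cds if b.genome_id in group_of[c.protein_id].genomes
            )
            s_b = sum(
                1 for c in b.cds if a.genome_id in group_of[c.protein_id].genomes
            )
            val = 100.0 * (s_a + s_b) / (n_prot[a.genome_id] + n_prot[b.genome_id])
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=ids, columns=ids)


def write_groups_table(
    groups: Iterable[ProteinGroup],
    proteins: Sequence[CDSRecord],
    path,
) -> None:
    """TSV group membership: group_id, protein_id, genome_id."""
    genome_of = {p.protein_id: p.genome_id for p in proteins}
    rows = []
    for g in groups:
        for m in sorted(g.members):
            rows.append((g.group_id, m, genome_of[m]))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("group_id\tprotein_id\tgenome_id\n")
        for gid, pid, genome in rows:
            fh.write(f"{gid}\t{pid}\t{genome}\n")
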
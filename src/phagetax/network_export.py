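"""Gene presence/absence matrix, genome-content distances and exports.

The binary matrix marks which protein groups occur in which genomes.  The
genome-content distance between two genomes is Jaccard-style by default:

    d(a, b) = |groups in exactly one of a, b| / |groups in at least one|

so groups absent from both genomes carry no signal for the pair.  The
alternative normalisation by the total number of groups (Hamming-style,
matching a "differences per gene site" reading) is available via
``denominator="all"``.  Distances are written as a NEXUS DISTANCES block
loadable by splits-network software.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .genome_io import GenomeRecord
from .protein_clustering import ProteinGroup

_NEXUS_RESERVED = set(" \t()[]{}/\\,;:=*'\"`<>^-+")


def presence_absence(
    genomes: Sequence[GenomeRecord],
    groups: Sequence[ProteinGroup],
) -> pd.DataFrame:
    """Binary genomes x groups matrix; cell = 1 iff the genome has at least
    one protein in the group.  Groups with no member in the listed genomes
    are dropped (no all-zero columns), and every genome must have a profile.
    """
    ids = [g.genome_id for g in genomes]
    id_set = set(ids)
    cols = []
    data = []
    for grp in groups:
        hit = grp.genomes & id_set
        if not hit:
            continue
        cols.append(grp.group_id)
        data.append([gid in hit for gid in ids])
    if not cols:
        raise ValueError("no protein groups overlap the given genomes")
    mat = pd.DataFrame(
        np.array(data, dtype=bool).T, index=ids, columns=cols
    )
    empty = [gid for gid in ids if not mat.loc[gid].any()]
    if empty:
        raise ValueError(f"genomes with empty gene profile: {empty}")
    return mat


def content_distance(
    pa: pd.DataFrame, denominator: str = "union"
) -> pd.DataFrame:
    """Symmetric genome-content distance matrix in [0, 1] (see module doc)."""
    if pa.shape[0] < 2:
        raise ValueError("need at least 2 genomes")
    if not pa.values.any(axis=1).all():
        empty = list(pa.index[~pa.values.any(axis=1)])
        raise ValueError(f"genomes with empty gene profile: {empty}")
    x = pa.values.astype(bool)
    if denominator == "union":
        d = pdist(x, metric="jaccard")
    elif denominator == "all":
        d = pdist(x, metric="hamming")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return pd.DataFrame(squareform(d), index=pa.index, columns=pa.index)


def _nexus_label(label: str) -> str:
    if set(label) & _NEXUS_RESERVED:
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus_distances(
    dist: pd.DataFrame, path: str | Path
) -> None:
    """Write a NEXUS file with TAXA and DISTANCES blocks (lower triangle).

    Byte-deterministic for fixed input; duplicate taxon labels are an error.
    """
    ids = list(dist.index)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxa labels")
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"    DIMENSIONS NTAX={len(ids)};"]
    lines.append(
        "    TAXLABELS " + " ".join(_nexus_label(t) for t in ids) + ";"
    )
    lines += [
        "END;",
        "",
        "BEGIN DISTANCES;",
        f"    DIMENSIONS NTAX={len(ids)};",
        "    FORMAT TRIANGLE=LOWER DIAGONAL LABELS=LEFT;",
        "    MATRIX",
    ]
    for i, t in enumerate(ids):
        row = " ".join(f"{dist.iloc[i, j]:.6f}" for j in range(i + 1))
        lines.append(f"    {_nexus_label(t)} {row}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_nexus_distances(path: str | Path) -> pd.DataFrame:
    """Parse a NEXUS DISTANCES block written by :func:`write_nexus_distances`."""
    text = Path(path).read_text()
    in_matrix = False
    labels: list[str] = []
    rows: list[list[float]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if line.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if line == ";" or line.upper().startswith("END"):
                break
            parts = _split_nexus_row(line)
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    n = len(labels)
    mat = np.zeros((n, n))
    for i, row in enumerate(rows):
        for j, v in enumerate(row):
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=labels, columns=labels)


def _split_nexus_row(line: str) -> list[str]:
    if line.startswith("'"):
        end = line.index("'", 1)
        while end + 1 < len(line) and line[end + 1] == "'":
            end = line.index("'", end + 2)
        label = line[1:end].replace("''", "'")
        rest = line[end + 1 :].split()
        return [label] + rest
    return line.split()


def write_heatmap_table(
    shared: pd.DataFrame,
    order: Sequence[str],
    cluster_of: dict[str, str] | None = None,
    path: str | Path = "heatmap.tsv",
) -> pd.DataFrame:
    """Shared-content matrix permuted to dendrogram leaf order, written as
    TSV with a leading cluster colour-key column."""
    if sorted(order) != sorted(shared.index):
        raise ValueError("order is not a permutation of the genome ids")
    mat = shared.loc[list(order), list(order)]
    out = mat.copy()
    key = [cluster_of.get(g, "") if cluster_of else "" for g in order]
    out.insert(0, "cluster", key)
    out.to_csv(path, sep="\t", float_format="%.1f")
    return mat
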
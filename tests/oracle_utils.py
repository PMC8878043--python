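"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: nucleotide merged
identities are checked against biotite's exhaustive Smith-Waterman; protein
pair decisions against biotite local alignment (the package itself uses
Biopython's PairwiseAligner); protein grouping against a brute-force
all-pairs + union-find construction; ORF calling against an enumerate-all-
candidates scanner.
"""

from __future__ import annotations

import numpy as np
from biotite.sequence import NucleotideSequence, ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

_NT_MATRIX = SubstitutionMatrix(
    NucleotideSequence.alphabet_unamb,
    NucleotideSequence.alphabet_unamb,
    np.where(np.eye(4, dtype=bool), 2, -3).astype(np.int32),
)
_PROT_MATRIX = SubstitutionMatrix.std_protein_matrix()  # BLOSUM62


def sw_nt_identities(query: str, subject: str) -> int:
    """Identity count of the optimal local alignment (+2/-3, gaps 5/2)."""
    alns = align_optimal(
        NucleotideSequence(query),
        NucleotideSequence(subject),
        _NT_MATRIX,
        gap_penalty=(-5, -2),
        local=True,
        max_number=1,
    )
    if not alns or alns[0].score <= 0:
        return 0
    aln = alns[0]
    trace = aln.trace
    ident = 0
    for i, j in trace:
        if i >= 0 and j >= 0 and query[i] == subject[j]:
            ident += 1
    return ident


def biotite_pair_match(
    p: str, q: str, min_identity: float = 0.35, min_coverage: float = 0.50
) -> tuple[bool, float, float]:
    """Protein pair decision via biotite (independent of the implementation)."""
    alns = align_optimal(
        ProteinSequence(p),
        ProteinSequence(q),
        _PROT_MATRIX,
        gap_penalty=(-11, -1),
        local=True,
        max_number=1,
    )
    if not alns or alns[0].score <= 0:
        return False, 0.0, 0.0
    trace = alns[0].trace
    columns = trace.shape[0]
    ident = sum(
        1 for i, j in trace if i >= 0 and j >= 0 and p[i] == q[j]
    )
    sp = trace[:, 0][trace[:, 0] >= 0]
    sq = trace[:, 1][trace[:, 1] >= 0]
    span_p = int(sp.max() - sp.min() + 1)
    span_q = int(sq.max() - sq.min() + 1)
    identity = ident / columns
    coverage = min(span_p / len(p), span_q / len(q))
    return identity >= min_identity and coverage >= min_coverage, identity, coverage


def brute_force_groups(proteins, min_identity=0.35, min_coverage=0.50):
    """All-pairs protein grouping: biotite pair decisions + union-find.

    No length prefilter, no transitive shortcuts.  Returns a set of
    frozensets of protein_ids.
    """
    parent = {p.protein_id: p.protein_id for p in proteins}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            ok, _, _ = biotite_pair_match(
                proteins[i].aa_sequence,
                proteins[j].aa_sequence,
                min_identity,
                min_coverage,
            )
            if ok:
                ri, rj = find(proteins[i].protein_id), find(proteins[j].protein_id)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[str, set[str]] = {}
    for p in proteins:
        comps.setdefault(find(p.protein_id), set()).add(p.protein_id)
    return {frozenset(c) for c in comps.values()}


def gotoh_local_score(p: str, q: str, matrix, open_cost=11, extend_cost=1) -> int:
    """Plain-python affine-gap Smith-Waterman score (tiny inputs only)."""
    n, m = len(p), len(q)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - extend_cost)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - extend_cost)
            s = matrix[p[i - 1], q[j - 1]]
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def enumerate_orfs(seq: str, min_len_nt: int = 120):
    """Every (start, end, strand) ORF by exhaustive candidate enumeration.

    For each start codon, the ORF runs to the next in-frame stop; among
    candidates sharing a stop only the longest survives.  Constructed
    differently from the package's scanner on purpose.
    """
    from phagetax.genome_io import reverse_complement

    stops = {"TAA", "TAG", "TGA"}
    starts = {"ATG", "GTG", "TTG"}

    def forward(s):
        found = {}
        for pos in range(len(s) - 2):
            if s[pos : pos + 3] not in starts:
                continue
            stop = None
            for sp in range(pos + 3, len(s) - 2, 3):
                if s[sp : sp + 3] in stops:
                    stop = sp
                    break
            if stop is None:
                continue
            length = stop + 3 - pos
            if length < min_len_nt:
                continue
            key = (pos % 3, stop)
            if key not in found or found[key][1] - found[key][0] < length:
                found[key] = (pos, stop + 3)
        return list(found.values())

    out = [(s, e, "+") for s, e in forward(seq)]
    rc = reverse_complement(seq)
    L = len(seq)
    out += [(L - e, L - s, "-") for s, e in forward(rc)]
    return sorted(out)
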
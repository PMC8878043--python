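"""Low-level seed-and-extend machinery for nucleotide local alignment.

Strategy (BLAST-like initial phase): exact k-mer seed matches between query
and subject are grouped by diagonal, nearby seeds on a diagonal define an
extension window, and within each window all maximal-scoring ungapped
segments above the score floor are reported.  N never matches anything.

The segment scan is compiled with numba; everything else is vectorised
numpy.  All steps are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Seeds on the same diagonal further apart than this start a new window.
_WINDOW_GAP = 250
#: Window padding on each side.  Must stay below _WINDOW_GAP / 2 so windows
#: on the same diagonal never overlap (would duplicate segments).
_WINDOW_PAD = 100

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes 0..3, N -> 4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp_codes(enc: np.ndarray) -> np.ndarray:
    return _COMP[enc][::-1]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers plus a validity mask (no N)."""
    n = enc.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(k):
        window = enc[i : i + n].astype(np.int64)
        codes = codes * 4 + np.where(window == 4, 0, window)
        valid &= enc[i : i + n] != 4
    return codes, valid


def seed_matches(
    q_enc: np.ndarray, s_enc: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """All (query_pos, subject_pos) pairs with an exact k-mer match."""
    q_codes, q_valid = _kmer_codes(q_enc, k)
    s_codes, s_valid = _kmer_codes(s_enc, k)
    if q_codes.size == 0 or s_codes.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    s_pos = np.nonzero(s_valid)[0]
    s_sorted_idx = np.argsort(s_codes[s_pos], kind="stable")
    s_pos = s_pos[s_sorted_idx]
    s_keys = s_codes[s_pos]
    q_pos = np.nonzero(q_valid)[0]
    q_keys = q_codes[q_pos]
    left = np.searchsorted(s_keys, q_keys, side="left")
    right = np.searchsorted(s_keys, q_keys, side="right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    qq = np.repeat(q_pos, counts)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    ss = s_pos[np.repeat(left, counts) + (np.arange(total) - offsets)]
    return qq, ss


def _windows(
    q_pos: np.ndarray,
    s_pos: np.ndarray,
    k: int,
    len_q: int,
    len_s: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Group seeds by diagonal into padded, clipped extension windows."""
    diag = q_pos - s_pos
    order = np.lexsort((q_pos, diag))
    d = diag[order]
    q = q_pos[order]
    if d.size == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e, e
    new = np.empty(d.size, dtype=bool)
    new[0] = True
    new[1:] = (np.diff(d) != 0) | (np.diff(q) > _WINDOW_GAP)
    starts = np.nonzero(new)[0]
    ends = np.append(starts[1:], d.size)
    w_diag = d[starts]
    # query range covered by both sequences on this diagonal
    lo = np.maximum(0, w_diag)
    hi = np.minimum(len_q, len_s + w_diag)
    w_start = np.clip(q[starts] - _WINDOW_PAD, lo, hi)
    w_end = np.clip(q[ends - 1] + k + _WINDOW_PAD, lo, hi)
    return w_diag, w_start, w_end


@njit(cache=True)
def _scan_windows(
    q_enc,
    s_enc,
    w_diag,
    w_start,
    w_end,
    match_score,
    mismatch_score,
    min_score,
    out_qs,
    out_qe,
    out_id,
    out_sc,
    out_dg,
):  # pragma: no cover - exercised via find_hsps
    n_out = 0
    for w in range(w_diag.shape[0]):
        dg = w_diag[w]
        end = w_end[w]
        i = w_start[w]
        seg_start = -1
        cur = 0
        best = 0
        best_end = -1
        while i < end:
            qb = q_enc[i]
            hit = qb == s_enc[i - dg] and qb < 4
            if seg_start < 0:
                if hit:
                    seg_start = i
                    cur = match_score
                    best = cur
                    best_end = i
                i += 1
                continue
            cur += match_score if hit else mismatch_score
            if cur > best:
                best = cur
                best_end = i
            if cur <= 0:
                if best >= min_score:
                    length = best_end + 1 - seg_start
                    out_qs[n_out] = seg_start
                    out_qe[n_out] = best_end + 1
                    out_id[n_out] = (best - mismatch_score * length) // (
                        match_score - mismatch_score
                    )
                    out_sc[n_out] = best
                    out_dg[n_out] = dg
                    n_out += 1
                    i = best_end + 1
                else:
                    i += 1
                seg_start = -1
                cur = 0
                best = 0
                best_end = -1
            else:
                i += 1
        if seg_start >= 0 and best >= min_score:
            length = best_end + 1 - seg_start
            out_qs[n_out] = seg_start
            out_qe[n_out] = best_end + 1
            out_id[n_out] = (best - mismatch_score * length) // (
                match_score - mismatch_score
            )
            out_sc[n_out] = best
            out_dg[n_out] = dg
            n_out += 1
    return n_out


def ungapped_segments(
    q_enc: np.ndarray,
    s_enc: np.ndarray,
    k: int,
    match_score: int,
    mismatch_score: int,
    min_score: int,
) -> np.ndarray:
    """High-scoring ungapped segments between two encoded sequences.

    Returns an (n, 5) int64 array of rows
    ``(q_start, q_end, s_start, identities, score)`` with half-open query
    coordinates; ``s_start = q_start - diagonal``.
    """
    q_pos, s_pos = seed_matches(q_enc, s_enc, k)
    if q_pos.size == 0:
        return np.empty((0, 5), dtype=np.int64)
    w_diag, w_start, w_end = _windows(
        q_pos, s_pos, k, len(q_enc), len(s_enc)
    )
    total = int((w_end - w_start).sum())
    # each emitted segment needs >= min_score/match_score matching columns
    cap = total // max(1, min_score // match_score) + w_diag.size + 8
    out = np.empty((5, cap), dtype=np.int64)
    n = _scan_windows(
        q_enc,
        s_enc,
        w_diag,
        w_start,
        w_end,
        np.int64(match_score),
        np.int64(mismatch_score),
        np.int64(min_score),
        out[0],
        out[1],
        out[2],
        out[3],
        out[4],
    )
    qs, qe, ident, score, dg = (out[i][:n] for i in range(5))
    res = np.empty((n, 5), dtype=np.int64)
    res[:, 0] = qs
    res[:, 1] = qe
    res[:, 2] = qs - dg
    res[:, 3] = ident
    res[:, 4] = score
    return res
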
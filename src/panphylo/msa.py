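"""Progressive protein multiple alignment for codon-alignment guidance.

A small profile-based progressive aligner: pairwise guide distances from
shared 3-mer counts, average-linkage guide tree, and profile-profile
Gotoh alignment with BLOSUM62 scores, affine gaps and free terminal gaps.
Free terminal gaps matter here because 5'-truncated transcripts yield
CDS sequences missing their amino-terminal region; they should align as a
suffix without paying terminal gap penalties.

Sequence sets in this pipeline are small (<= a dozen rows, a few hundred
residues), so the dynamic programs are dense numpy row sweeps.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

_BLOSUM = substitution_matrices.load("BLOSUM62")
ALPHABET = str(_BLOSUM.alphabet)  # includes X and *
_A = len(ALPHABET)
_RES_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_B = np.array(_BLOSUM, dtype=np.float32)

GAP_OPEN = -11.0
GAP_EXTEND = -1.0


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile (ncol x alphabet); gaps contribute nothing."""
    ncol = len(rows[0])
    prof = np.zeros((ncol, _A), dtype=np.float32)
    for row in rows:
        for j, aa in enumerate(row):
            if aa != "-":
                prof[j, _RES_INDEX.get(aa, _RES_INDEX["X"])] += 1.0
    counts = prof.sum(axis=1, keepdims=True)
    counts[counts == 0] = 1.0
    return prof / counts


def _align_profiles(p1: np.ndarray, p2: np.ndarray) -> tuple[list[int], list[int]]:
    """Gotoh alignment of two profiles with free terminal gaps.

    Returns parallel path lists: for each alignment column, the source
    column index in profile 1 / profile 2, or -1 for a gap.
    """
    n, m = p1.shape[0], p2.shape[0]
    S = (p1 @ _B) @ p2.T  # expected substitution score per column pair
    NEG = np.float32(-1e9)
    M = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    Ix = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in profile 2 (consumes p1)
    Iy = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in profile 1 (consumes p2)
    M[0, 0] = 0.0
    Ix[1:, 0] = 0.0  # free leading terminal gaps
    Iy[0, 1:] = 0.0
    for i in range(1, n + 1):
        prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev[:-1] + S[i - 1]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] + GAP_OPEN, Ix[i - 1, 1:] + GAP_EXTEND)
        Ix[i, 0] = 0.0
        # horizontal state via prefix-max scan:
        # Iy[i,j] = max_{k<j} M[i,k] + GAP_OPEN + GAP_EXTEND*(j-k-1)
        run = np.maximum.accumulate(M[i, :-1] - GAP_EXTEND * np.arange(m))
        Iy[i, 1:] = run + GAP_OPEN + GAP_EXTEND * np.arange(m)
    # free trailing terminal gaps: end anywhere on last row/column
    end_scores = np.maximum(np.maximum(M, Ix), Iy)
    last_row = end_scores[n, :]
    last_col = end_scores[:, m]
    if last_row.max() >= last_col.max():
        i, j = n, int(last_row.argmax())
    else:
        i, j = int(last_col.argmax()), m
    path1: list[int] = []
    path2: list[int] = []
    tail1 = list(range(i, n))
    tail2 = list(range(j, m))
    # traceback; state transitions mirror the recurrences exactly
    state = max(
        (("M", M[i, j]), ("Ix", Ix[i, j]), ("Iy", Iy[i, j])), key=lambda t: t[1]
    )[0]
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                break
            prev = max(
                (("M", M[i - 1, j - 1]), ("Ix", Ix[i - 1, j - 1]), ("Iy", Iy[i - 1, j - 1])),
                key=lambda t: t[1],
            )[0]
            path1.append(i - 1)
            path2.append(j - 1)
            i, j, state = i - 1, j - 1, prev
        elif state == "Ix":
            if j == 0 or i == 0:
                break  # leading free gap region
            state = (
                "M"
                if M[i - 1, j] + GAP_OPEN >= Ix[i - 1, j] + GAP_EXTEND
                else "Ix"
            )
            path1.append(i - 1)
            path2.append(-1)
            i -= 1
        else:  # Iy: chained from some M[i,k] on the same row
            if i == 0 or j == 0:
                break
            state = (
                "M"
                if M[i, j - 1] + GAP_OPEN >= Iy[i, j - 1] + GAP_EXTEND
                else "Iy"
            )
            path1.append(-1)
            path2.append(j - 1)
            j -= 1
    head1 = list(range(i))
    head2 = list(range(j))
    path1.reverse()
    path2.reverse()
    out1 = head1 + [-1] * len(head2) + path1 + tail1 + [-1] * len(tail2)
    out2 = [-1] * len(head1) + head2 + path2 + [-1] * len(tail1) + tail2
    return out1, out2


def _merge(rows1: list[str], rows2: list[str]) -> tuple[list[str], list[str]]:
    path1, path2 = _align_profiles(_profile(rows1), _profile(rows2))

    def expand(rows: list[str], path: list[int]) -> list[str]:
        return [
            "".join(row[k] if k >= 0 else "-" for k in path) for row in rows
        ]

    return expand(rows1, path1), expand(rows2, path2)


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    sa = {a[i : i + k] for i in range(max(len(a) - k + 1, 1))}
    sb = {b[i : i + k] for i in range(max(len(b) - k + 1, 1))}
    denom = min(len(sa), len(sb)) or 1
    return 1.0 - len(sa & sb) / denom


def align_proteins(seqs: Mapping[str, str]) -> dict[str, str]:
    """Progressive multiple alignment; returns id -> gapped row."""
    ids = sorted(seqs)
    if len(ids) == 1:
        return {ids[0]: seqs[ids[0]]}
    if len(ids) == 2:
        r1, r2 = _merge([seqs[ids[0]]], [seqs[ids[1]]])
        return {ids[0]: r1[0], ids[1]: r2[0]}
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(seqs[ids[i]], seqs[ids[j]])
    tree = to_tree(linkage(squareform(dm, checks=False), method="average"))

    def rec(node) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            return [ids[node.id]], [seqs[ids[node.id]]]
        lids, lrows = rec(node.left)
        rids, rrows = rec(node.right)
        lrows, rrows = _merge(lrows, rrows)
        return lids + rids, lrows + rrows

    out_ids, out_rows = rec(tree)
    return dict(zip(out_ids, out_rows))
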
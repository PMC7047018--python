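"""Pairwise similarity search and reciprocal-best-hit (RBH) orthology.

Target-species CDS sequences are compared to the anchor reference species
(sorghum-like) with a thresholded local alignment: a hit is kept only when
it reaches 70% identity and covers 50% of the query.  A transcript and a
reference gene are called putative orthologs when each is the other's
unique top-scoring hit in the bidirectional search.

The aligner backend is pluggable.  The default is an affine-gap local
aligner (match +1, mismatch -1, gap open -2, gap extend -1).  An exact
all-vs-all scan is quadratic in the number of sequences, so the search
first collapses byte-identical query sequences (redundant isoforms are
common in consensus transcript sets) and then restricts alignment to
subjects sharing at least one exact 12-mer with the query — the same
seed-and-extend shortcut seeded DNA search tools rely on.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import Align

HIT_COLUMNS = [
    "query_id", "subject_id", "score", "identity", "coverage",
    "qstart", "qend", "sstart", "send",
]

DEFAULT_MIN_IDENTITY = 0.70
DEFAULT_MIN_COVERAGE = 0.50
SEED_K = 12


@dataclass(frozen=True)
class RbhPair:
    target_transcript_id: str
    reference_gene_id: str
    score: float


class LocalAligner:
    """Affine-gap local DNA aligner producing score, identity, coverage, spans."""

    def __init__(self, match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -2.0, gap_extend: float = -1.0):
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.match_score = match
        self._aligner.mismatch_score = mismatch
        self._aligner.open_gap_score = gap_open
        self._aligner.extend_gap_score = gap_extend

    def align(self, query: str, subject: str) -> Optional[dict]:
        """Best local alignment, or None when nothing aligns with positive score."""
        alns = self._aligner.align(query, subject)
        if len(alns) == 0 or alns.score <= 0:
            return None
        aln = alns[0]
        qblocks, sblocks = aln.aligned
        matches = 0
        aligned_q = 0
        for (qs, qe), (ss, se) in zip(qblocks, sblocks):
            aligned_q += qe - qs
            matches += sum(
                1 for a, b in zip(query[qs:qe], subject[ss:se]) if a == b
            )
        # columns of the local alignment, gap columns included
        ncols = aln.length
        return {
            "score": float(aln.score),
            "identity": matches / ncols if ncols else 0.0,
            "coverage": aligned_q / len(query),
            "qstart": int(qblocks[0][0]),
            "qend": int(qblocks[-1][1]),
            "sstart": int(sblocks[0][0]),
            "send": int(sblocks[-1][1]),
        }


def _kmer_set(seq: str, k: int = SEED_K) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def _seed_candidates(
    query: str,
    kmer_index: Mapping[str, Sequence[str]],
    max_candidates: int,
) -> list[str]:
    counts: dict[str, int] = defaultdict(int)
    for i in range(len(query) - SEED_K + 1):
        for sid in kmer_index.get(query[i : i + SEED_K], ()):
            counts[sid] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [sid for sid, _ in ranked[:max_candidates]]


def similarity_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    aligner: Optional[LocalAligner] = None,
    max_candidates: int = 4,
    seed_filter: bool = True,
) -> pd.DataFrame:
    """All query-vs-subject local alignments meeting both thresholds.

    With ``seed_filter`` (default) only subjects sharing an exact 12-mer
    with the query are aligned, at most ``max_candidates`` per query ranked
    by shared-seed count; set ``seed_filter=False`` for an exhaustive scan.
    Identical query sequences are aligned once and the hits replicated.
    """
    aligner = aligner or LocalAligner()
    kmer_index: dict[str, list[str]] = defaultdict(list)
    if seed_filter:
        for sid in sorted(subjects):
            for kmer in _kmer_set(subjects[sid]):
                kmer_index[kmer].append(sid)

    # collapse byte-identical queries
    by_seq: dict[str, list[str]] = defaultdict(list)
    for qid in sorted(queries):
        by_seq[queries[qid]].append(qid)

    rows = []
    for seq, qids in sorted(by_seq.items(), key=lambda kv: kv[1][0]):
        if seed_filter:
            cand = _seed_candidates(seq, kmer_index, max_candidates)
        else:
            cand = sorted(subjects)
        for sid in cand:
            res = aligner.align(seq, subjects[sid])
            if res is None:
                continue
            if res["identity"] < min_identity or res["coverage"] < min_coverage:
                continue
            for qid in qids:
                rows.append({"query_id": qid, "subject_id": sid, **res})
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sort_values(["query_id", "score"], ascending=[True, False]).reset_index(drop=True)


def bidirectional_hits(
    target_cds: Mapping[str, str],
    reference_cds: Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    aligner: Optional[LocalAligner] = None,
    max_candidates: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward (target->reference) and reverse hit tables from one alignment pass.

    Each pair is aligned once; identity and spans are direction-independent,
    while coverage is recomputed on the respective query's length, so both
    tables apply the thresholds exactly as two separate searches would.
    """
    aligner = aligner or LocalAligner()
    raw = similarity_search(
        target_cds, reference_cds,
        min_identity=min_identity, min_coverage=0.0,
        aligner=aligner, max_candidates=max_candidates,
    )
    fwd_rows, rev_rows = [], []
    for row in raw.itertuples(index=False):
        if row.coverage >= min_coverage:
            fwd_rows.append(row._asdict())
        s_cov = (row.send - row.sstart) / len(reference_cds[row.subject_id])
        if s_cov >= min_coverage:
            rev_rows.append({
                "query_id": row.subject_id, "subject_id": row.query_id,
                "score": row.score, "identity": row.identity, "coverage": s_cov,
                "qstart": row.sstart, "qend": row.send,
                "sstart": row.qstart, "send": row.qend,
            })
    fwd = pd.DataFrame(fwd_rows, columns=HIT_COLUMNS)
    rev = pd.DataFrame(rev_rows, columns=HIT_COLUMNS)
    fwd = fwd.sort_values(["query_id", "score"], ascending=[True, False]).reset_index(drop=True)
    rev = rev.sort_values(["query_id", "score"], ascending=[True, False]).reset_index(drop=True)
    return fwd, rev


def _unique_best(
    hits: pd.DataFrame, subject_seqs: Optional[Mapping[str, str]] = None
) -> dict[str, str]:
    """query -> subject when the top score is unique; tied queries get no best.

    When ``subject_seqs`` is given, ties between byte-identical subject
    sequences (redundant isoforms of one locus) are not treated as
    ambiguous: the lexicographically smallest id wins.  Ties between
    distinct sequences still disqualify the query.
    """
    best: dict[str, str] = {}
    for qid, sub in hits.groupby("query_id"):
        top = sub["score"].max()
        winners = sorted(sub.loc[sub["score"] == top, "subject_id"].unique())
        if len(winners) > 1 and subject_seqs is not None:
            if len({subject_seqs[w] for w in winners}) == 1:
                winners = winners[:1]
        if len(winners) == 1:
            best[qid] = winners[0]
    return best


def reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    seqs_a: Optional[Mapping[str, str]] = None,
    seqs_b: Optional[Mapping[str, str]] = None,
) -> set[RbhPair]:
    """Pairs (a, b) where b is a's unique best subject and vice versa.

    ``seqs_a``/``seqs_b`` optionally resolve score ties among
    byte-identical sequences (see ``_unique_best``).
    """
    best_ab = _unique_best(hits_ab, seqs_b)
    best_ba = _unique_best(hits_ba, seqs_a)
    pairs = set()
    score_of = {
        (r.query_id, r.subject_id): r.score for r in hits_ab.itertuples(index=False)
    }
    for a, b in best_ab.items():
        if best_ba.get(b) == a:
            pairs.add(RbhPair(a, b, score_of[(a, b)]))
    return pairs


def select_representative(
    pairs: set[RbhPair],
    cds_lengths: Mapping[str, int],
) -> dict[str, str]:
    """One representative transcript per reference gene.

    Highest RBH score wins; ties go to the longer CDS, then to the
    lexicographically smallest transcript id.
    """
    by_gene: dict[str, list[RbhPair]] = defaultdict(list)
    for p in pairs:
        by_gene[p.reference_gene_id].append(p)
    out = {}
    for gene, plist in by_gene.items():
        out[gene] = min(
            plist,
            key=lambda p: (-p.score, -cds_lengths[p.target_transcript_id], p.target_transcript_id),
        ).target_transcript_id
    return out


def compare_annotation_lengths(
    pairs: Sequence[tuple[str, str]],
    lengths_a: Mapping[str, int],
    lengths_b: Mapping[str, int],
) -> tuple[int, int]:
    """(n pairs with len_a > len_b, n pairs with len_a <= len_b)."""
    n_longer = n_other = 0
    for a, b in pairs:
        if a not in lengths_a or b not in lengths_b:
            raise KeyError(f"missing length for pair ({a!r}, {b!r})")
        if lengths_a[a] > lengths_b[b]:
            n_longer += 1
        else:
            n_other += 1
    return n_longer, n_other
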
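"""Longest-ORF CDS calling from consensus long-read transcripts.

Consensus transcripts from oligo-dT IsoSeq libraries are polyA-oriented but
frequently 5'-truncated, so a CDS caller that insists on an in-frame ATG
systematically truncates real coding sequence.  The rule implemented here
instead requires only an in-frame stop codon: each forward reading frame is
partitioned into segments bounded by stop codons (and the sequence start),
every segment that ends in a stop is a candidate ORF, and the single longest
candidate across the three forward frames is reported as the CDS.  A start
codon anywhere in frame within the segment is recorded but not required,
which may append untranslated codons to the 5' end of the putative CDS.

The six-frame stop scan is a separate, deliberately weaker check used only
for quality triage of raw transcripts: a transcript with no stop codon in
any of its six reading frames indicates a sequencing error or incomplete
3' coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # {"TAA", "TAG", "TGA"}

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _CODON_TO_AA[_stop] = "*"


@dataclass(frozen=True)
class Transcript:
    """A consensus cDNA sequence with a species tag."""

    id: str
    species: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"transcript {self.id!r} has empty sequence")


@dataclass(frozen=True)
class CdsRecord:
    """A single CDS called from a transcript by the longest-ORF rule.

    ``frame_offset`` is the 0-based offset of the first CDS base on the
    transcript; ``cds_seq`` always ends with a stop codon and has length
    divisible by three.  ``has_start`` records whether an in-frame ATG
    exists anywhere within the segment; ``has_stop`` is always True by
    construction.  ``complete`` is filled in by ``classify_completeness``.
    """

    transcript_id: str
    frame_offset: int
    cds_seq: str
    protein_seq: str
    has_start: bool
    has_stop: bool = True
    complete: bool = False

    def __post_init__(self) -> None:
        if len(self.cds_seq) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        if self.cds_seq[-3:] not in STOP_CODONS:
            raise ValueError("CDS does not end with a stop codon")


def _codons(seq: str, frame: int) -> Iterator[tuple[int, str]]:
    """Yield (offset, codon) for complete codons of ``seq`` in ``frame``."""
    for i in range(frame, len(seq) - 2, 3):
        yield i, seq[i : i + 3]


def _stop_terminated_segments(seq: str, frame: int) -> Iterator[tuple[int, int]]:
    """Half-open [start, end) nt intervals of stop-terminated segments.

    A segment runs from the sequence start (or the base after the previous
    in-frame stop) up to and including an in-frame stop codon.
    """
    start = frame
    for i, codon in _codons(seq, frame):
        if codon in STOP_CODONS:
            yield start, i + 3
            start = i + 3


def find_cds(t: Transcript) -> Optional[CdsRecord]:
    """Call the single longest stop-terminated ORF on the forward strand.

    Returns None when no forward frame contains a stop codon.  Ties on
    length are broken toward the 5'-most segment, then the lowest frame.
    """
    seq = t.seq.upper()
    best: Optional[tuple[int, int, int]] = None  # (-length, start, frame)
    for frame in range(3):
        for start, end in _stop_terminated_segments(seq, frame):
            key = (-(end - start), start, frame)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    length, start, frame = -best[0], best[1], best[2]
    cds = seq[start : start + length]
    has_start = any(codon == "ATG" for _, codon in _codons(cds, 0))
    protein = _translate(cds[:-3])
    return CdsRecord(
        transcript_id=t.id,
        frame_offset=start,
        cds_seq=cds,
        protein_seq=protein,
        has_start=has_start,
    )


def classify_completeness(c: CdsRecord, t: Transcript) -> bool:
    """A CDS is complete iff it has start and stop and spans >= 60% of the transcript."""
    return bool(c.has_start and c.has_stop and len(c.cds_seq) >= 0.6 * len(t.seq))


def six_frame_stop_check(seq: str) -> bool:
    """True iff any of the six reading frames contains a stop codon."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    for strand_seq in (seq, reverse_complement(seq)):
        for frame in range(3):
            if any(c in STOP_CODONS for _, c in _codons(strand_seq, frame)):
                return True
    return False


def _translate(seq: str) -> str:
    """Standard-code translation; codons containing N/IUPAC ambiguity -> X."""
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


def translate_cds(c: CdsRecord) -> str:
    """Translate a CDS, dropping the terminal stop and keeping internal '*'.

    Internal stops can occur in reference annotations and are preserved so
    the discard ledger can detect them.
    """
    if len(c.cds_seq) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    return _translate(c.cds_seq[:-3])


def translate_frame(seq: str) -> str:
    """Translate an arbitrary in-frame CDS string (length % 3 == 0), '*' for stops."""
    if len(seq) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    return _translate(seq)


def call_cds_batch(transcripts: Iterable[Transcript]) -> dict[str, CdsRecord]:
    """Call CDS for many transcripts; transcripts with no ORF are omitted."""
    out: dict[str, CdsRecord] = {}
    for t in transcripts:
        rec = find_cds(t)
        if rec is not None:
            out[t.id] = rec
    return out
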
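"""WGD combination sampling, protein-guided codon alignment, block
filtering, and the discard ledger.

Groups where the maize-like or teff-like lineage retained its
whole-genome-duplication pair would give gene trees with extra leaves, so
each retained pair is sampled one copy at a time: 1, 2 or 4 combination
alignments per group depending on how many lineages retained a pair.

Codon alignments are protein-guided: CDS sequences are translated, the
proteins aligned, and each gap expanded to a whole-codon gap, so removing
the gaps from any row reproduces the input CDS exactly.

Block filtering reimplements the classic conserved-block heuristic on the
protein projection (majority-conservation thresholds, no gap columns, long
nonconserved runs break blocks, short blocks dropped, flanks must be
highly conserved); the retained protein columns are expanded back to codon
columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .orf_extract import six_frame_stop_check, translate_frame
from .orthogroups import RETAINED, OrthoGroup
from . import msa
from .species import REFERENCE_SPECIES, TARGET_SPECIES, WGD_LINEAGES

LEDGER_REASONS = (
    "internal_stop_reference",
    "no_stop_six_frames",
    "missing_annotation",
    "short_alignment",
    "outgroup_not_monophyletic",
)

DEFAULT_MIN_ALIGNMENT_NT = 900  # 300 codons

# block-filter defaults (protein columns)
MAX_NONCONSERVED_RUN = 8
MIN_BLOCK_LEN = 10
HIGH_CONSERVATION_FRACTION = 0.85


@dataclass(frozen=True)
class CombinationSample:
    group_id: str
    combo_index: int  # 1-based
    leaf_selection: dict[str, str]  # species -> single gene/transcript id

    def __post_init__(self):
        for sp, sel in self.leaf_selection.items():
            if not isinstance(sel, str):
                raise ValueError(f"sample must hold one id per species ({sp})")


@dataclass
class CodonAlignment:
    rows: dict[str, str]  # species -> gapped CDS
    protein_rows: dict[str, str]  # species -> gapped protein (guide MSA)
    source: Optional[CombinationSample] = None
    mask: Optional[np.ndarray] = None  # retained codon-alignment column indices

    @property
    def ncol(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def masked_length(self) -> int:
        return 0 if self.mask is None else int(len(self.mask))

    def masked_rows(self) -> dict[str, str]:
        idx = self.mask if self.mask is not None else np.arange(self.ncol)
        return {sp: "".join(row[i] for i in idx) for sp, row in self.rows.items()}


@dataclass(frozen=True)
class LedgerEntry:
    group_id: str
    reason: str
    detail: str = ""

    def __post_init__(self):
        if self.reason not in LEDGER_REASONS:
            raise ValueError(f"unknown ledger reason {self.reason!r}")


def enumerate_combinations(g: OrthoGroup) -> list[CombinationSample]:
    """All single-copy leaf selections across retained WGD pairs.

    1 sample when both lineages fractionated, 2 when exactly one retained
    its pair, 4 when both did.  Only groups represented in all three
    target species are aligned.
    """
    if g.category != 3:
        raise ValueError(
            f"group {g.group_id}: combinations only defined for category-3 "
            f"groups (got category {g.category})"
        )
    wgd_species = set(WGD_LINEAGES.values())
    fixed: dict[str, str] = {}
    for sp in REFERENCE_SPECIES + TARGET_SPECIES:
        ids = g.members.get(sp, [])
        if sp not in wgd_species and ids:
            fixed[sp] = ids[0]
    choice_species = [sp for sp in sorted(wgd_species) if g.members.get(sp)]
    choices = [g.members[sp] for sp in choice_species]
    samples = []
    for k, combo in enumerate(product(*choices), start=1):
        sel = dict(fixed)
        sel.update(dict(zip(choice_species, combo)))
        samples.append(CombinationSample(g.group_id, k, sel))
    return samples


def codon_align(
    cds_by_species: Mapping[str, str],
    protein_aligner: Callable[[Mapping[str, str]], dict[str, str]] = msa.align_proteins,
    source: Optional[CombinationSample] = None,
) -> CodonAlignment:
    """Protein-guided codon alignment of one combination sample.

    Each CDS must end in a stop codon and have length divisible by three.
    The terminal stop codons are appended as three trailing ungapped
    columns so that degapping any row reproduces the full input CDS.
    """
    proteins = {}
    for sp, cds in cds_by_species.items():
        if len(cds) % 3 != 0:
            raise ValueError(f"{sp}: CDS length not divisible by 3")
        proteins[sp] = translate_frame(cds[:-3])
    aligned = protein_aligner(proteins)
    rows = {}
    for sp, prot_row in aligned.items():
        cds = cds_by_species[sp]
        out = []
        pos = 0
        for aa in prot_row:
            if aa == "-":
                out.append("---")
            else:
                out.append(cds[pos : pos + 3])
                pos += 3
        if pos != len(cds) - 3:
            raise ValueError(f"{sp}: protein/CDS length mismatch")
        out.append(cds[-3:])
        rows[sp] = "".join(out)
    return CodonAlignment(rows=rows, protein_rows=dict(aligned), source=source)


def filter_blocks(
    a: CodonAlignment,
    max_nonconserved_run: int = MAX_NONCONSERVED_RUN,
    min_block_len: int = MIN_BLOCK_LEN,
    high_fraction: float = HIGH_CONSERVATION_FRACTION,
) -> np.ndarray:
    """Conserved-block mask as sorted codon-alignment column indices.

    Computed on the protein projection: a column is conserved when its
    majority residue count reaches floor(n/2)+1, highly conserved when it
    reaches ceil(high_fraction * n); ties make a column nonconserved.  Any
    gap makes a column non-retainable.  Runs longer than
    ``max_nonconserved_run`` nonconserved columns break candidate blocks;
    block flanks are trimmed back to highly conserved columns; blocks
    shorter than ``min_block_len`` are dropped.  Surviving protein columns
    expand to their three codon columns.
    """
    prot = list(a.protein_rows.values())
    n = len(prot)
    ncol_p = len(prot[0]) if prot else 0
    conserved = np.zeros(ncol_p, dtype=bool)
    highly = np.zeros(ncol_p, dtype=bool)
    has_gap = np.zeros(ncol_p, dtype=bool)
    maj_threshold = n // 2 + 1
    high_threshold = math.ceil(high_fraction * n)
    for j in range(ncol_p):
        col = [row[j] for row in prot]
        if "-" in col:
            has_gap[j] = True
            continue
        counts: dict[str, int] = {}
        for aa in col:
            counts[aa] = counts.get(aa, 0) + 1
        top = max(counts.values())
        if list(counts.values()).count(top) > 1:
            continue  # majority tie -> nonconserved
        if top >= maj_threshold:
            conserved[j] = True
        if top >= high_threshold and top >= maj_threshold:
            highly[j] = True
    noncons = ~conserved  # gap columns are nonconserved too

    # break at runs of > max_nonconserved_run contiguous nonconserved columns
    breakpoints = np.zeros(ncol_p, dtype=bool)
    run_start = None
    for j in range(ncol_p + 1):
        if j < ncol_p and noncons[j]:
            if run_start is None:
                run_start = j
        else:
            if run_start is not None and (j - run_start) > max_nonconserved_run:
                breakpoints[run_start:j] = True
            run_start = None

    kept_protein_cols: list[int] = []
    j = 0
    while j < ncol_p:
        if breakpoints[j]:
            j += 1
            continue
        end = j
        while end < ncol_p and not breakpoints[end]:
            end += 1
        block = list(range(j, end))
        # trim flanks to highly conserved columns
        while block and not highly[block[0]]:
            block.pop(0)
        while block and not highly[block[-1]]:
            block.pop()
        if len(block) >= min_block_len:
            kept_protein_cols.extend(c for c in block if not has_gap[c])
        j = end
    mask = np.array(
        sorted(c * 3 + k for c in kept_protein_cols for k in range(3)), dtype=int
    )
    return mask


def apply_ledger(
    groups: Sequence[OrthoGroup],
    reference_cds: Mapping[str, Mapping[str, str]],
    group_transcripts: Mapping[str, Sequence[tuple[str, str]]],
    alignments: Optional[Mapping[str, Sequence[CodonAlignment]]] = None,
    min_alignment_nt: int = DEFAULT_MIN_ALIGNMENT_NT,
) -> list[LedgerEntry]:
    """Screen groups for the discard reasons and the short-alignment flag.

    ``reference_cds`` maps species -> {gene id -> CDS}; ``group_transcripts``
    maps group id -> [(transcript id, raw sequence), ...] for the target
    transcripts assigned to the group's loci.  ``alignments`` (masked)
    contribute ``short_alignment`` entries, which define the long-alignment
    subset rather than discarding a group from the all-genes analysis.
    """
    entries: list[LedgerEntry] = []
    for g in groups:
        for sp in REFERENCE_SPECIES:
            cds_map = reference_cds.get(sp, {})
            for gid in g.members.get(sp, []):
                cds = cds_map.get(gid)
                if cds is None:
                    entries.append(LedgerEntry(
                        g.group_id, "missing_annotation",
                        f"{sp}:{gid} listed in synteny but absent from CDS set",
                    ))
                    continue
                if "*" in translate_frame(cds[:-3]):
                    entries.append(LedgerEntry(
                        g.group_id, "internal_stop_reference",
                        f"{sp}:{gid} translates with internal stop",
                    ))
        for tid, seq in group_transcripts.get(g.group_id, []):
            if not six_frame_stop_check(seq):
                entries.append(LedgerEntry(
                    g.group_id, "no_stop_six_frames",
                    f"transcript {tid} has no stop codon in any frame",
                ))
    if alignments is not None:
        for g in groups:
            alns = alignments.get(g.group_id, [])
            short = [
                a.source.combo_index if a.source else i + 1
                for i, a in enumerate(alns)
                if a.masked_length < min_alignment_nt
            ]
            if short:
                entries.append(LedgerEntry(
                    g.group_id, "short_alignment",
                    "masked length < %d nt for combination(s) %s"
                    % (min_alignment_nt, ",".join(map(str, short))),
                ))
    return entries


def discarded_group_ids(entries: Sequence[LedgerEntry]) -> set[str]:
    """Groups excluded from alignment entirely (reasons a-c)."""
    hard = {"internal_stop_reference", "no_stop_six_frames", "missing_annotation"}
    return {e.group_id for e in entries if e.reason in hard}
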
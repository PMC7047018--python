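"""End-to-end driver: transcripts -> CDS -> RBH -> groups -> alignments ->
trees -> topology census.

The driver consumes a dataset (in memory or a directory written by the
synthetic generator): per-target-species transcript FASTA, one CDS FASTA
per reference species, and the sorghum-anchored synteny TSV.  It exists so
tests, the analysis scripts and the acceptance script all execute the very
same code path.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import align_qc, homology, orthogroups, tree_topology
from .align_qc import CodonAlignment, LedgerEntry
from .orf_extract import CdsRecord, call_cds_batch
from .species import ANCHOR_SPECIES, OUTGROUP, TARGET_SPECIES
from .synthetic_data import SimResult, TruthSet


@dataclass
class PipelineConfig:
    min_identity: float = homology.DEFAULT_MIN_IDENTITY
    min_coverage: float = homology.DEFAULT_MIN_COVERAGE
    min_alignment_nt: int = align_qc.DEFAULT_MIN_ALIGNMENT_NT
    # looser thresholds for assigning transcripts without a callable CDS
    # to loci (the redundancy-collapse step), not for orthology calls
    assignment_min_identity: float = 0.5
    assignment_min_coverage: float = 0.3
    max_candidates: int = 4


@dataclass
class PipelineResult:
    cds_records: dict[str, dict[str, CdsRecord]]
    rbh_pairs: dict[str, set]
    representatives: dict[str, dict[str, str]]
    locus_assignment: dict[str, str]  # transcript id -> anchor gene id
    groups: list
    category_tally: tuple[int, int, int, int]
    ledger: list[LedgerEntry]
    alignments: dict[str, list[CodonAlignment]]
    accepted: list  # (group_id, combo_index, rooted dendropy tree)
    rejected: list  # (group_id, combo_index)
    census_all: list
    census_long: list
    masked_lengths: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def trees_built(self) -> int:
        return len(self.accepted) + len(self.rejected)

    def isoform_counts(self) -> pd.DataFrame:
        """Transcripts assigned per anchor gene, by target species."""
        counts: dict[tuple[str, str], int] = defaultdict(int)
        for tid, gene in self.locus_assignment.items():
            sp = tid.split("_")[0]
            counts[(sp, gene)] += 1
        rows = [
            {"species": sp, "anchor_gene": gene, "n_transcripts": n}
            for (sp, gene), n in sorted(counts.items())
        ]
        return pd.DataFrame(rows, columns=["species", "anchor_gene", "n_transcripts"])


def run_pipeline(
    data: SimResult, config: Optional[PipelineConfig] = None
) -> PipelineResult:
    config = config or PipelineConfig()
    anchor_cds = data.reference_cds[ANCHOR_SPECIES]

    # 1. CDS calling per target species
    cds_records = {
        sp: call_cds_batch(data.transcripts[sp]) for sp in TARGET_SPECIES
    }

    # 2. RBH orthology against the anchor + locus assignment of transcripts
    rbh_pairs: dict[str, set] = {}
    representatives: dict[str, dict[str, str]] = {}
    locus_assignment: dict[str, str] = {}
    for sp in TARGET_SPECIES:
        cds_seqs = {tid: rec.cds_seq for tid, rec in cds_records[sp].items()}
        fwd, rev = homology.bidirectional_hits(
            cds_seqs, anchor_cds,
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            max_candidates=config.max_candidates,
        )
        pairs = homology.reciprocal_best_hits(fwd, rev, seqs_a=cds_seqs, seqs_b=anchor_cds)
        rbh_pairs[sp] = pairs
        lengths = {tid: len(seq) for tid, seq in cds_seqs.items()}
        representatives[sp] = homology.select_representative(pairs, lengths)
        # redundancy collapse: each transcript's best-scoring anchor locus
        for tid, sub in fwd.groupby("query_id"):
            top = sub.loc[sub["score"].idxmax()]
            locus_assignment[tid] = top["subject_id"]
        # transcripts without a callable CDS (e.g. no stop codon in any
        # frame) are assigned by aligning the raw transcript, loosely
        no_cds = {
            t.id: t.seq
            for t in data.transcripts[sp]
            if t.id not in cds_records[sp]
        }
        if no_cds:
            # exhaustive scan: heavily corrupted sequences may share no
            # exact seed with their locus, and this set is tiny
            loose = homology.similarity_search(
                no_cds, anchor_cds,
                min_identity=config.assignment_min_identity,
                min_coverage=config.assignment_min_coverage,
                seed_filter=False,
            )
            for tid, sub in loose.groupby("query_id"):
                top = sub.loc[sub["score"].idxmax()]
                locus_assignment[tid] = top["subject_id"]

    # 3. ortholog groups and category tally
    rbh_maps = representatives
    groups = orthogroups.build_groups(data.synteny, rbh_maps)
    category_tally = orthogroups.tally_categories(groups)

    # 4. discard ledger (reasons a-c) on all groups
    anchor_to_group = {}
    for g in groups:
        for aid in g.members.get(ANCHOR_SPECIES, []):
            anchor_to_group[aid] = g.group_id
    group_transcripts: dict[str, list[tuple[str, str]]] = defaultdict(list)
    raw_seq = {
        t.id: t.seq for sp in TARGET_SPECIES for t in data.transcripts[sp]
    }
    for tid, gene in locus_assignment.items():
        gid = anchor_to_group.get(gene)
        if gid is not None:
            group_transcripts[gid].append((tid, raw_seq[tid]))
    for gid in group_transcripts:
        group_transcripts[gid].sort()
    ledger = align_qc.apply_ledger(
        groups, data.reference_cds, group_transcripts,
        min_alignment_nt=config.min_alignment_nt,
    )
    discarded = align_qc.discarded_group_ids(ledger)

    # 5. combination samples, codon alignments, block filtering
    alignments: dict[str, list[CodonAlignment]] = {}
    masked_lengths: dict[tuple[str, int], int] = {}
    aligned_groups = []
    for g in groups:
        if g.category != 3 or g.group_id in discarded:
            continue
        aligned_groups.append(g)
        samples = align_qc.enumerate_combinations(g)
        alns = []
        for sample in samples:
            cds_by_species = {}
            for sp, sel in sample.leaf_selection.items():
                if sp in TARGET_SPECIES:
                    cds_by_species[sp] = cds_records[sp][sel].cds_seq
                else:
                    cds_by_species[sp] = data.reference_cds[sp][sel]
            a = align_qc.codon_align(cds_by_species, source=sample)
            a.mask = align_qc.filter_blocks(a)
            masked_lengths[(g.group_id, sample.combo_index)] = a.masked_length
            alns.append(a)
        alignments[g.group_id] = alns
    ledger += align_qc.apply_ledger(
        aligned_groups, data.reference_cds, group_transcripts,
        alignments=alignments, min_alignment_nt=config.min_alignment_nt,
    )

    # 6. trees, outgroup screen, census
    accepted, rejected = [], []
    for gid in sorted(alignments):
        for a in alignments[gid]:
            if a.masked_length < 3 or len(a.rows) < 4:
                continue
            tree = tree_topology.build_tree(a)
            rooted = tree_topology.check_outgroup_and_root(tree, OUTGROUP)
            combo = a.source.combo_index
            if rooted is None:
                rejected.append((gid, combo))
                ledger.append(LedgerEntry(
                    gid, "outgroup_not_monophyletic",
                    f"combination {combo}: outgroup pair not sister to rest",
                ))
            else:
                accepted.append((gid, combo, rooted))

    census_all = tree_topology.census(accepted)
    long_accepted = [
        (gid, combo, t)
        for gid, combo, t in accepted
        if masked_lengths[(gid, combo)] >= config.min_alignment_nt
    ]
    census_long = tree_topology.census(long_accepted)

    return PipelineResult(
        cds_records=cds_records,
        rbh_pairs=rbh_pairs,
        representatives=representatives,
        locus_assignment=locus_assignment,
        groups=groups,
        category_tally=category_tally,
        ledger=ledger,
        alignments=alignments,
        accepted=accepted,
        rejected=rejected,
        census_all=census_all,
        census_long=census_long,
        masked_lengths=masked_lengths,
    )


def evaluate_rbh(
    result: PipelineResult, data: SimResult
) -> dict[str, float]:
    """Precision/recall of RBH pairs against the simulated ortholog map.

    A pair (transcript, anchor gene) is correct when the transcript's true
    group equals the anchor gene's synteny group.  Recall is measured over
    expressed loci: (group, species) combinations that emitted at least
    one transcript with a callable CDS.
    """
    truth: TruthSet = data.truth
    anchor_to_group = {}
    for row in data.synteny.itertuples(index=False):
        d = row._asdict()
        for aid in str(d[ANCHOR_SPECIES]).split(","):
            if aid and aid != ".":
                anchor_to_group[aid] = d["group_id"]
    n_pairs = n_correct = 0
    recovered: set[tuple[str, str]] = set()
    for sp in TARGET_SPECIES:
        for p in result.rbh_pairs[sp]:
            n_pairs += 1
            true_group, true_sp = truth.ortholog_map[p.target_transcript_id]
            if anchor_to_group.get(p.reference_gene_id) == true_group and true_sp == sp:
                n_correct += 1
                recovered.add((true_group, sp))
    expressed: set[tuple[str, str]] = set()
    callable_tids = {
        tid for sp in TARGET_SPECIES for tid in result.cds_records[sp]
    }
    for tid, (gid, sp) in truth.ortholog_map.items():
        if tid in callable_tids:
            expressed.add((gid, sp))
    precision = n_correct / n_pairs if n_pairs else 0.0
    recall = len(recovered) / len(expressed) if expressed else 0.0
    return {
        "n_pairs": float(n_pairs),
        "precision": precision,
        "recall": recall,
        "n_expressed_loci": float(len(expressed)),
    }
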
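"""Synthetic multi-species transcript datasets with known ground truth.

Emulates the study design the pipeline is built for: eight reference
species with annotated CDS sets joined by a sorghum-anchored synteny
table, and three target species represented only by redundant,
partially 5'-truncated consensus transcripts.  Per gene the generator

1. draws a random stop-free root CDS and evolves it along a gene tree
   (the species tree, or an NNI-perturbed copy with probability
   ``discord_rate``) under Jukes-Cantor substitution, resampling any
   mutation that would create an in-frame stop;
2. duplicates the locus in the maize-like and teff-like WGD lineages,
   retaining the pair with the lineage's retention probability;
3. emits Poisson(isoform_mean)+1 transcript copies per expressed
   target-species locus, padding the CDS with UTRs that carry stop
   codons in every frame (so the planted CDS is the longest ORF by
   construction) and truncating a 5' fraction of some isoforms, as
   oligo-dT capture of fragmented mRNA does;
4. plants sequence defects (internal stop in a reference CDS, a
   stop-free transcript, a deleted reference annotation) at configured
   rates so discard-ledger recovery can be tested exactly.

Determinism: one master seed; per-gene substreams are derived from
(seed, stream, gene index) so changing the gene count never reshuffles
earlier genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .orf_extract import Transcript
from .species import (
    DEFAULT_RETENTION,
    MISSING_CELL,
    REFERENCE_SPECIES,
    SPECIES_TOPOLOGY,
    TARGET_SPECIES,
    WGD_LINEAGES,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOP_CODON_IDS = frozenset(
    16 * "ACGT".index(c[0]) + 4 * "ACGT".index(c[1]) + "ACGT".index(c[2])
    for c in ("TAA", "TAG", "TGA")
)
_NONSTOP_CODON_IDS = np.array(
    [k for k in range(64) if k not in _STOP_CODON_IDS], dtype=int
)
_STOP_CODON_ID_ARRAY = np.array(sorted(_STOP_CODON_IDS), dtype=int)

UTR5_LEN = 100
UTR3_LEN = 150
# TAA at relative offsets 0, 4, 8: a stop in every frame wherever placed
_STOP_SEED = "TAACTAACTAA"

DEFAULT_DEFECT_RATES = {
    "internal_stop_reference": 0.022,
    "no_stop_six_frames": 0.012,
    "missing_annotation": 0.011,
}


@dataclass
class SimConfig:
    n_genes: int = 200
    discord_rate: float = 0.3
    nni_moves: int = 1
    retention_prob_per_wgd_lineage: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RETENTION)
    )
    expression_dropout: float = 0.39
    isoform_mean: float = 10.0
    truncation_prob: float = 0.2
    defect_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEFECT_RATES)
    )
    root_cds_codons: int = 500
    branch_length: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.discord_rate, self.expression_dropout, self.truncation_prob,
            *self.retention_prob_per_wgd_lineage.values(),
            *self.defect_rates.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.root_cds_codons < 34:
            raise ValueError("root_cds_codons must be >= 34 (>= 102 nt)")


@dataclass
class TruthSet:
    gene_trees: list[str]  # rooted newick per gene
    ortholog_map: dict[str, tuple[str, str]]  # transcript id -> (group, species)
    wgd_status: dict[str, dict[str, str]]  # group -> lineage -> status
    planted_defects: list[tuple[str, str]]  # (group, reason)

    def to_json(self) -> str:
        payload = {
            "gene_trees": self.gene_trees,
            "ortholog_map": {k: list(v) for k, v in sorted(self.ortholog_map.items())},
            "wgd_status": self.wgd_status,
            "planted_defects": [list(x) for x in self.planted_defects],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        return cls(
            gene_trees=d["gene_trees"],
            ortholog_map={k: tuple(v) for k, v in d["ortholog_map"].items()},
            wgd_status=d["wgd_status"],
            planted_defects=[tuple(x) for x in d["planted_defects"]],
        )


@dataclass
class SimResult:
    truth: TruthSet
    transcripts: dict[str, list[Transcript]]  # target species -> transcripts
    reference_cds: dict[str, dict[str, str]]  # reference species -> id -> CDS
    synteny: pd.DataFrame
    out_dir: Optional[Path] = None


def build_species_tree(config: Optional[SimConfig] = None) -> dendropy.Tree:
    """The fixed literature topology with uniform branch lengths."""
    config = config or SimConfig()
    tree = dendropy.Tree.get(data=SPECIES_TOPOLOGY, schema="newick")
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = config.branch_length
    return tree


def _outgroup_clade_node(tree: dendropy.Tree):
    from .species import OUTGROUP

    for node in tree.preorder_internal_node_iter():
        if {l.taxon.label for l in node.leaf_iter()} == set(OUTGROUP):
            return node
    raise ValueError("tree lacks the outgroup clade")


def _eligible_nni_edges(tree: dendropy.Tree) -> list:
    """Internal edges strictly inside the ingroup subtree.

    Excludes edges incident to the root and the outgroup clade so no move
    can disrupt the outgroup pair or its sister position.
    """
    og = _outgroup_clade_node(tree)
    edges = []
    for node in tree.preorder_internal_node_iter():
        parent = node.parent_node
        if parent is None or parent is tree.seed_node:
            continue
        if node is og or og in node.ancestor_iter():
            continue
        edges.append(node)
    return edges


def _nni(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """One random NNI move on an eligible internal edge, in place."""
    candidates = _eligible_nni_edges(tree)
    if not candidates:
        return
    v = candidates[int(rng.integers(len(candidates)))]
    u = v.parent_node
    siblings = [c for c in u.child_nodes() if c is not v]
    s = siblings[int(rng.integers(len(siblings)))]
    children = v.child_nodes()
    c = children[int(rng.integers(len(children)))]
    u.remove_child(s)
    v.remove_child(c)
    u.add_child(c)
    v.add_child(s)


def simulate_gene_trees(
    tree: dendropy.Tree, config: SimConfig
) -> list[dendropy.Tree]:
    """Per-gene trees: the species topology, NNI-perturbed with prob discord_rate."""
    out = []
    for i in range(config.n_genes):
        rng = np.random.default_rng([config.seed, 0, i])
        gt = tree.clone(depth=1)
        if rng.random() < config.discord_rate:
            for _ in range(config.nni_moves):
                _nni(gt, rng)
        out.append(gt)
    return out


def _evolve_branch(
    seq: np.ndarray, branch_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Jukes-Cantor evolution of a coding sequence (terminal stop fixed).

    Sites mutate with p = 3/4 (1 - exp(-4/3 b)); any mutation creating an
    in-frame internal stop codon is resampled (the whole codon is redrawn
    from the 61 sense codons).
    """
    p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * branch_length))
    child = seq.copy()
    coding_len = len(seq) - 3
    mutate = rng.random(coding_len) < p
    idx = np.nonzero(mutate)[0]
    child[idx] = (child[idx] + rng.integers(1, 4, size=len(idx))) % 4
    codons = child[:coding_len].reshape(-1, 3)
    ids = 16 * codons[:, 0] + 4 * codons[:, 1] + codons[:, 2]
    bad = np.nonzero(np.isin(ids, _STOP_CODON_ID_ARRAY))[0]
    for b in bad:
        new = _NONSTOP_CODON_IDS[int(rng.integers(len(_NONSTOP_CODON_IDS)))]
        codons[b] = [new // 16, (new // 4) % 4, new % 4]
    return child


def _seq_to_str(seq: np.ndarray) -> str:
    return BASES[seq].tobytes().decode()


def _random_root_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    coding = _NONSTOP_CODON_IDS[rng.integers(len(_NONSTOP_CODON_IDS), size=n_codons - 1)]
    stop = _STOP_CODON_ID_ARRAY[int(rng.integers(3))]
    ids = np.concatenate([coding, [stop]])
    out = np.empty(3 * n_codons, dtype=int)
    out[0::3] = ids // 16
    out[1::3] = (ids // 4) % 4
    out[2::3] = ids % 4
    return out


def _random_utr(length: int, rng: np.random.Generator, seed_at_start: bool) -> str:
    utr = list(BASES[rng.integers(4, size=length)].tobytes().decode())
    if seed_at_start:
        utr[: len(_STOP_SEED)] = _STOP_SEED
    else:
        utr[-len(_STOP_SEED):] = _STOP_SEED
    return "".join(utr)


def _evolve_gene(
    gene_tree: dendropy.Tree, root_seq: np.ndarray, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Leaf sequences and, for WGD species, the sequence at the leaf's parent."""
    node_seq: dict[int, np.ndarray] = {id(gene_tree.seed_node): root_seq}
    leaves: dict[str, np.ndarray] = {}
    parents: dict[str, np.ndarray] = {}
    wgd_species = set(WGD_LINEAGES.values())
    for node in gene_tree.preorder_node_iter():
        if node is gene_tree.seed_node:
            continue
        parent_seq = node_seq[id(node.parent_node)]
        seq = _evolve_branch(parent_seq, node.edge.length or 0.0, rng)
        node_seq[id(node)] = seq
        if node.is_leaf():
            label = node.taxon.label
            leaves[label] = seq
            if label in wgd_species:
                parents[label] = parent_seq
    return leaves, parents


def evolve_and_emit(
    gene_trees: list[dendropy.Tree],
    config: SimConfig,
    out_dir: Optional[str | Path] = None,
) -> SimResult:
    """Evolve sequences along each gene tree and emit the dataset.

    Writes per-target-species transcript FASTA, per-reference-species CDS
    FASTA, the synteny TSV and the truth JSON when ``out_dir`` is given;
    the same data are returned in memory either way.
    """
    transcripts: dict[str, list[Transcript]] = {sp: [] for sp in TARGET_SPECIES}
    reference_cds: dict[str, dict[str, str]] = {sp: {} for sp in REFERENCE_SPECIES}
    synteny_rows = []
    ortholog_map: dict[str, tuple[str, str]] = {}
    wgd_status: dict[str, dict[str, str]] = {}
    planted: list[tuple[str, str]] = []
    lineages = sorted(WGD_LINEAGES)

    for i, gt in enumerate(gene_trees):
        group_id = f"g{i:04d}"
        rng_e = np.random.default_rng([config.seed, 1, i])
        rng_d = np.random.default_rng([config.seed, 2, i])
        root = _random_root_cds(config.root_cds_codons, rng_e)
        leaves, wgd_parents = _evolve_gene(gt, root, rng_e)

        # WGD duplicate copies, retained per lineage retention probability
        copies: dict[str, list[np.ndarray]] = {sp: [leaves[sp]] for sp in REFERENCE_SPECIES}
        wgd_status[group_id] = {}
        for lineage in lineages:
            sp = WGD_LINEAGES[lineage]
            dup = _evolve_branch(
                wgd_parents[sp], config.branch_length, rng_e
            )
            retained = bool(
                rng_e.random() < config.retention_prob_per_wgd_lineage[lineage]
            )
            if retained:
                copies[sp].append(dup)
            wgd_status[group_id][lineage] = "retained" if retained else "fractionated"

        row = {"group_id": group_id}
        for sp in REFERENCE_SPECIES:
            ids = []
            for k, seq in enumerate(copies[sp]):
                gid = f"{sp}_{group_id}" + ("" if k == 0 else "b")
                reference_cds[sp][gid] = _seq_to_str(seq)
                ids.append(gid)
            row[sp] = ",".join(ids)
        synteny_rows.append(row)

        # target-species transcript emission
        iso_by_sp: dict[str, list[str]] = {}
        for sp in TARGET_SPECIES:
            if rng_e.random() < config.expression_dropout:
                continue
            n_iso = int(rng_e.poisson(config.isoform_mean)) + 1
            cds = _seq_to_str(leaves[sp])
            utr5 = _random_utr(UTR5_LEN, rng_e, seed_at_start=False)
            utr3 = _random_utr(UTR3_LEN, rng_e, seed_at_start=True)
            base = utr5 + cds + utr3
            ids = []
            for k in range(n_iso):
                seq = base
                if rng_e.random() < config.truncation_prob:
                    cut = int(rng_e.random() * 0.5 * len(seq))
                    seq = seq[cut:]
                tid = f"{sp}_{group_id}_t{k}"
                transcripts[sp].append(Transcript(id=tid, species=sp, seq=seq))
                ortholog_map[tid] = (group_id, sp)
                ids.append(tid)
            iso_by_sp[sp] = ids

        # planted defects
        if rng_d.random() < config.defect_rates.get("internal_stop_reference", 0.0):
            sp = "Oropetium"
            gid = f"{sp}_{group_id}"
            cds = list(reference_cds[sp][gid])
            codon = 1 + int(rng_d.integers(config.root_cds_codons - 2))
            cds[3 * codon : 3 * codon + 3] = "TAA"
            reference_cds[sp][gid] = "".join(cds)
            planted.append((group_id, "internal_stop_reference"))
        if rng_d.random() < config.defect_rates.get("no_stop_six_frames", 0.0):
            candidates = [sp for sp in TARGET_SPECIES if len(iso_by_sp.get(sp, [])) >= 2]
            if candidates:
                sp = candidates[int(rng_d.integers(len(candidates)))]
                tid = iso_by_sp[sp][-1]
                tlist = transcripts[sp]
                for k in range(len(tlist) - 1, -1, -1):
                    if tlist[k].id == tid:
                        tlist[k] = Transcript(
                            id=tid, species=sp, seq=tlist[k].seq.replace("T", "C")
                        )
                        break
                planted.append((group_id, "no_stop_six_frames"))
        if rng_d.random() < config.defect_rates.get("missing_annotation", 0.0):
            sp = "Brachypodium"
            del reference_cds[sp][f"{sp}_{group_id}"]
            planted.append((group_id, "missing_annotation"))

    synteny = pd.DataFrame(synteny_rows, columns=["group_id", *REFERENCE_SPECIES])
    truth = TruthSet(
        gene_trees=[t.as_string(schema="newick").strip() for t in gene_trees],
        ortholog_map=ortholog_map,
        wgd_status=wgd_status,
        planted_defects=planted,
    )
    result = SimResult(
        truth=truth,
        transcripts=transcripts,
        reference_cds=reference_cds,
        synteny=synteny,
        out_dir=Path(out_dir) if out_dir else None,
    )
    if out_dir is not None:
        _write_dataset(result, Path(out_dir))
    return result


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def _write_dataset(result: SimResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for sp in TARGET_SPECIES:
        _write_fasta(
            out_dir / f"transcripts_{sp}.fasta",
            [(t.id, t.seq) for t in result.transcripts[sp]],
        )
    for sp in REFERENCE_SPECIES:
        _write_fasta(
            out_dir / f"cds_{sp}.fasta",
            sorted(result.reference_cds[sp].items()),
        )
    result.synteny.to_csv(out_dir / "synteny.tsv", sep="\t", index=False)
    (out_dir / "truth.json").write_text(result.truth.to_json())


def load_dataset(out_dir: str | Path) -> SimResult:
    """Read a previously emitted dataset back into memory."""
    from Bio import SeqIO

    out_dir = Path(out_dir)
    transcripts = {
        sp: [
            Transcript(id=rec.id, species=sp, seq=str(rec.seq))
            for rec in SeqIO.parse(out_dir / f"transcripts_{sp}.fasta", "fasta")
        ]
        for sp in TARGET_SPECIES
    }
    reference_cds = {
        sp: {
            rec.id: str(rec.seq)
            for rec in SeqIO.parse(out_dir / f"cds_{sp}.fasta", "fasta")
        }
        for sp in REFERENCE_SPECIES
    }
    synteny = pd.read_csv(out_dir / "synteny.tsv", sep="\t", dtype=str)
    truth = TruthSet.from_json((out_dir / "truth.json").read_text())
    return SimResult(
        truth=truth,
        transcripts=transcripts,
        reference_cds=reference_cds,
        synteny=synteny,
        out_dir=out_dir,
    )


def simulate(config: SimConfig, out_dir: Optional[str | Path] = None) -> SimResult:
    """Species tree -> gene trees -> sequences, in one call."""
    tree = build_species_tree(config)
    gene_trees = simulate_gene_trees(tree, config)
    return evolve_and_emit(gene_trees, config, out_dir)
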
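"""Neighbor-joining trees, outgroup screening, topology census, bootstrap.

Reads the masked combination alignments written by 03_align_filter.py,
builds one tree per alignment, rejects trees where rice+brachypodium are
not a sister pair to everything else, tallies canonical topologies, and
averages bootstrap branch supports per topology class.
"""

import argparse
from pathlib import Path

from Bio import SeqIO

from panphylo.align_qc import CodonAlignment
from panphylo.species import SPECIES_TOPOLOGY
from panphylo.tree_topology import (
    bootstrap_support,
    build_tree,
    canonical_from_newick,
    census,
    census_table,
    check_outgroup_and_root,
)

ROOT = Path(__file__).resolve().parents[1]


def load_alignment(path: Path) -> CodonAlignment:
    rows = {r.id: str(r.seq) for r in SeqIO.parse(path, "fasta")}
    a = CodonAlignment(rows=rows, protein_rows={})
    import numpy as np

    a.mask = np.arange(a.ncol)  # rows are already masked
    return a


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--bootstrap-sample", type=int, default=10)
    ap.add_argument("--bootstrap-reps", type=int, default=50)
    args = ap.parse_args()

    aln_dir = ROOT / "results" / "alignments"
    out = ROOT / "results"
    alignments = []
    keys = []
    for path in sorted(aln_dir.glob("*.fasta")):
        gid, combo = path.stem.rsplit("_c", 1)
        alignments.append(load_alignment(path))
        keys.append((gid, int(combo)))

    accepted, rejected = [], []
    for (gid, combo), a in zip(keys, alignments):
        rooted = check_outgroup_and_root(build_tree(a))
        if rooted is None:
            rejected.append((gid, combo))
        else:
            accepted.append((gid, combo, rooted))
    print(f"{len(alignments)} trees built, {len(accepted)} accepted, "
          f"{len(rejected)} rejected by the outgroup screen")

    topologies = census(accepted)
    tab = census_table(topologies)
    tab.to_csv(out / "census_all.tsv", sep="\t", index=False)
    species_canonical = canonical_from_newick(SPECIES_TOPOLOGY)
    for _, row in tab.head(3).iterrows():
        marker = " <- species topology" if row["canonical"] == species_canonical else ""
        print(f"  rank {row['rank']}: {row['count']} trees ({row['percent']}%){marker}")

    n_sample = min(args.bootstrap_sample, len(alignments))
    supports = bootstrap_support(
        alignments, n_trees=n_sample, reps=args.bootstrap_reps, seed=args.seed
    )
    with open(out / "branch_supports.tsv", "w") as fh:
        fh.write("topology\tclade\tmean_support\n")
        for topo, sup in supports.items():
            for clade, val in sorted(sup.items(), key=lambda kv: sorted(kv[0])):
                fh.write(f"{topo}\t{'|'.join(sorted(clade))}\t{val:.1f}\n")
    if species_canonical in supports:
        vals = supports[species_canonical].values()
        print(f"bootstrap ({n_sample} groups x {args.bootstrap_reps} reps): mean "
              f"support on the species topology "
              f"{sum(vals)/len(vals):.1f}%")
    print("census in results/census_all.tsv, supports in results/branch_supports.tsv")


if __name__ == "__main__":
    main()
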
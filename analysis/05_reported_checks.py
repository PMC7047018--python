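"""Recompute the published summary counts of the original three-species
IsoSeq study from their printed components, through the package's own
tally, ledger and percentage conventions.

Every row of the output table is an arithmetic consistency check: the
inputs are printed counts, the value is recomputed by the package, and
the expectation is the printed headline number.
"""

from pathlib import Path

import pandas as pd

from panphylo.align_qc import LedgerEntry, discarded_group_ids
from panphylo.homology import compare_annotation_lengths
from panphylo.tree_topology import truncate_percent

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []

    cats = (2774, 1611, 2276, 5139)
    rows.append(("syntenic_groups_total", sum(cats), 11800))

    ledger = [LedgerEntry(f"g{i}", r) for i, r in enumerate(
        ["internal_stop_reference"] * 113
        + ["no_stop_six_frames"] * 61
        + ["missing_annotation"] * 57
    )]
    discarded = discarded_group_ids(ledger)
    rows.append(("discard_ledger_total", len(discarded), 231))
    rows.append(("groups_surviving_ledger", cats[3] - len(discarded), 4908))

    rows.append(("census_rank1_percent", truncate_percent(291, 684), 42.5))
    rows.append(("census_rank2_percent", truncate_percent(43, 684), 6.2))
    rows.append(("census_rank3_percent", truncate_percent(28, 684), 4.0))

    pairs = [(f"i{k}", f"m{k}") for k in range(13847)]
    la = {f"i{k}": (2 if k < 12347 else 1) for k in range(13847)}
    lb = {f"m{k}": 1 for k in range(13847)}
    n_longer, n_other = compare_annotation_lengths(pairs, la, lb)
    rows.append(("rbh_isoseq_longer", n_longer, 12347))
    rows.append(("rbh_length_comparison_total", n_longer + n_other, 13847))

    rows.append(("coverage_dichanthelium_pct", truncate_percent(7760, 11800), 65.7))
    rows.append(("coverage_hymenachne_pct", truncate_percent(6402, 11800), 54.2))
    rows.append(("aligned_dichanthelium_pct", truncate_percent(171465, 190632), 89.9))

    df = pd.DataFrame(rows, columns=["quantity", "recomputed", "printed"])
    df["consistent"] = df["recomputed"] == df["printed"]
    out = ROOT / "results" / "reported_checks.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"\n{int(df['consistent'].sum())}/{len(df)} checks consistent; "
          f"table in {out}")


if __name__ == "__main__":
    main()
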
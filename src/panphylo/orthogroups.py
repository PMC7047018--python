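"""Transitive ortholog groups from RBH maps joined with the synteny table.

Orthology is treated as transitive: a target-species transcript whose
reciprocal best hit is anchor gene g is considered orthologous to every
syntenic ortholog of g in the other reference species.  Groups are
anchored strictly on the sorghum-like species; each target species
contributes at most its single representative transcript per group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .species import (
    ANCHOR_SPECIES,
    MISSING_CELL,
    REFERENCE_SPECIES,
    TARGET_SPECIES,
    WGD_LINEAGES,
)

logger = logging.getLogger(__name__)

RETAINED = "retained"
FRACTIONATED = "fractionated"


@dataclass
class OrthoGroup:
    """One syntenic row joined with target-species representatives."""

    group_id: str
    members: dict[str, list[str]]  # species -> gene/transcript ids
    category: int = 0  # number of target species with a representative
    retention: dict[str, str] = field(default_factory=dict)  # lineage -> status

    def recompute(self) -> None:
        self.category = sum(
            1 for sp in TARGET_SPECIES if self.members.get(sp)
        )
        self.retention = {
            lineage: RETAINED if len(self.members.get(sp, [])) == 2 else FRACTIONATED
            for lineage, sp in WGD_LINEAGES.items()
        }


def read_synteny_table(path) -> pd.DataFrame:
    """Read the syntenic-ortholog TSV: group_id + one column per reference species."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING_CELL)
    if "group_id" not in df.columns:
        raise ValueError("synteny table must have a group_id column")
    return df


def _cell_ids(cell: str) -> list[str]:
    if cell is None or cell == MISSING_CELL or cell == "":
        return []
    return [x for x in cell.split(",") if x]


def build_groups(
    synteny: pd.DataFrame,
    rbh_maps: Mapping[str, Mapping[str, str]],
) -> list[OrthoGroup]:
    """One group per synteny row, with representatives joined via the anchor.

    ``rbh_maps`` maps target species -> {anchor_gene_id -> representative
    transcript id}.  Rows whose anchor cell is missing are skipped with a
    warning (they cannot be joined).
    """
    groups: list[OrthoGroup] = []
    for row in synteny.itertuples(index=False):
        rowd = row._asdict()
        anchor_ids = _cell_ids(rowd.get(ANCHOR_SPECIES, MISSING_CELL))
        if not anchor_ids:
            logger.warning("synteny row %s has no anchor (%s) id; skipped",
                           rowd.get("group_id"), ANCHOR_SPECIES)
            continue
        members: dict[str, list[str]] = {}
        for sp in REFERENCE_SPECIES:
            ids = _cell_ids(rowd.get(sp, MISSING_CELL))
            if ids:
                members[sp] = ids
        for sp in TARGET_SPECIES:
            rbh = rbh_maps.get(sp, {})
            reps = [rbh[g] for g in anchor_ids if g in rbh]
            if reps:
                members[sp] = reps[:1]  # single representative per group
        g = OrthoGroup(group_id=str(rowd["group_id"]), members=members)
        g.recompute()
        groups.append(g)
    return groups


def tally_categories(groups: Iterable[OrthoGroup]) -> tuple[int, int, int, int]:
    """Counts of groups with representatives in 0, 1, 2, 3 target species."""
    counts = [0, 0, 0, 0]
    for g in groups:
        counts[g.category] += 1
    return tuple(counts)


def screen_gene_list(
    groups: Sequence[OrthoGroup],
    anchor_gene_ids: Sequence[str],
) -> pd.DataFrame:
    """Presence report for a list of anchor genes (e.g. known C4 pathway genes).

    Unknown ids are reported with in_synteny=False rather than raising.
    """
    by_anchor: dict[str, OrthoGroup] = {}
    for g in groups:
        for aid in g.members.get(ANCHOR_SPECIES, []):
            by_anchor[aid] = g
    rows = []
    for aid in anchor_gene_ids:
        g = by_anchor.get(aid)
        row = {"anchor_gene": aid, "in_synteny": g is not None}
        for sp in TARGET_SPECIES:
            row[sp] = bool(g and g.members.get(sp))
        row["category"] = g.category if g else 0
        rows.append(row)
    return pd.DataFrame(rows)


def groups_to_frame(groups: Sequence[OrthoGroup]) -> pd.DataFrame:
    """Flatten groups to the TSV layout (one column per species, comma-joined)."""
    rows = []
    for g in groups:
        row = {"group_id": g.group_id}
        for sp in REFERENCE_SPECIES + TARGET_SPECIES:
            ids = g.members.get(sp, [])
            row[sp] = ",".join(ids) if ids else MISSING_CELL
        row["category"] = g.category
        for lineage in WGD_LINEAGES:
            row[f"retention_{lineage}"] = g.retention.get(lineage, FRACTIONATED)
        rows.append(row)
    return pd.DataFrame(rows)
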
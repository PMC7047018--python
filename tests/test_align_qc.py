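"""Combination sampling, codon alignment round-trips, block filtering and
the discard ledger."""

import random

import numpy as np
import pytest

from panphylo.align_qc import (
    CodonAlignment,
    apply_ledger,
    codon_align,
    discarded_group_ids,
    enumerate_combinations,
    filter_blocks,
)
from panphylo.orthogroups import OrthoGroup
from panphylo.species import ANCHOR_SPECIES, REFERENCE_SPECIES, TARGET_SPECIES

NONSTOP = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_cds(rng, n_codons):
    return "".join(rng.choice(NONSTOP) for _ in range(n_codons - 1)) + "TGA"


def make_group(maize_ids, teff_ids):
    members = {sp: [f"{sp}_x"] for sp in REFERENCE_SPECIES + TARGET_SPECIES}
    members["Zea"] = maize_ids
    members["Eragrostis"] = teff_ids
    g = OrthoGroup(group_id="g1", members=members)
    g.recompute()
    return g


class TestEnumerateCombinations:
    def test_both_fractionated_one_sample(self):
        assert len(enumerate_combinations(make_group(["z1"], ["e1"]))) == 1

    def test_one_retained_two_samples(self):
        samples = enumerate_combinations(make_group(["z1", "z2"], ["e1"]))
        assert len(samples) == 2
        assert {s.leaf_selection["Zea"] for s in samples} == {"z1", "z2"}

    def test_both_retained_four_samples(self):
        samples = enumerate_combinations(make_group(["z1", "z2"], ["e1", "e2"]))
        assert len(samples) == 4
        combos = {(s.leaf_selection["Zea"], s.leaf_selection["Eragrostis"]) for s in samples}
        assert combos == {("z1", "e1"), ("z1", "e2"), ("z2", "e1"), ("z2", "e2")}

    def test_combination_count_law(self):
        for maize in (["z1"], ["z1", "z2"]):
            for teff in (["e1"], ["e1", "e2"]):
                n = len(enumerate_combinations(make_group(maize, teff)))
                retained = (len(maize) == 2) + (len(teff) == 2)
                assert n == 2 ** retained and n in (1, 2, 4)

    def test_incomplete_group_rejected(self):
        g = make_group(["z1"], ["e1"])
        del g.members["Hymenachne"]
        g.recompute()
        with pytest.raises(ValueError):
            enumerate_combinations(g)


class TestCodonAlign:
    def test_identical_cds_gapless(self):
        rng = random.Random(0)
        cds = random_cds(rng, 40)
        a = codon_align({"A": cds, "B": cds})
        assert a.ncol == len(cds)
        assert a.rows["A"] == a.rows["B"] == cds

    def test_single_codon_insertion_makes_one_gap(self):
        rng = random.Random(1)
        left = [rng.choice(NONSTOP) for _ in range(20)]
        insert = rng.choice(NONSTOP)
        short = "".join(left) + "TGA"
        long = "".join(left[:10]) + insert + "".join(left[10:]) + "TGA"
        a = codon_align({"A": short, "B": long})
        assert a.rows["A"].count("-") == 3
        assert "---" in a.rows["A"]
        assert a.rows["B"].count("-") == 0

    def test_round_trip_on_random_groups(self):
        rng = random.Random(2)
        for _ in range(100):
            n = rng.randint(2, 6)
            base = random_cds(rng, rng.randint(34, 60))
            seqs = {}
            for k in range(n):
                # point-mutate the coding part a little
                chars = list(base)
                for _ in range(rng.randint(0, 10)):
                    i = rng.randrange(len(base) - 3)
                    chars[i] = rng.choice("ACGT")
                seqs[f"s{k}"] = "".join(chars)
            a = codon_align(seqs)
            for k, cds in seqs.items():
                assert a.rows[k].replace("-", "") == cds

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            codon_align({"A": "ATGA", "B": "ATGTGA"})


def protein_alignment_fixture(columns):
    """Build a CodonAlignment whose protein projection is the given list of
    column strings (one string per column, one char per row)."""
    nrows = len(columns[0])
    rows = {}
    prots = {}
    for r in range(nrows):
        prots[f"s{r}"] = "".join(col[r] for col in columns)
    back = {"-": "---"}
    codon_of = {aa: c for aa, c in zip("ACDEFGHIKLMNPQRSTVWY", NONSTOP)}
    for rid, prot in prots.items():
        rows[rid] = "".join(back.get(aa, codon_of.get(aa, "GCA")) for aa in prot)
    return CodonAlignment(rows=rows, protein_rows=prots)


class TestFilterBlocks:
    def test_identical_gapless_alignment_fully_retained(self):
        cols = ["AAAA"] * 30
        a = protein_alignment_fixture(cols)
        mask = filter_blocks(a)
        assert len(mask) == 3 * 30

    def test_gap_column_excluded(self):
        cols = ["AAAA"] * 15 + ["-AAA"] + ["AAAA"] * 15
        a = protein_alignment_fixture(cols)
        mask = filter_blocks(a)
        gap_cols = {15 * 3, 15 * 3 + 1, 15 * 3 + 2}
        assert gap_cols.isdisjoint(set(mask.tolist()))

    def test_nine_column_nonconserved_run_breaks_blocks(self):
        # conserved block (12) + 9 nonconserved + conserved block (12):
        # the run is > 8 so it breaks and is excluded; both flanking
        # blocks are >= 10 columns and survive
        conserved = ["AAAA"] * 12
        nonconserved = ["ACDE"] * 9  # all residues distinct -> tie -> nonconserved
        cols = conserved + nonconserved + conserved
        a = protein_alignment_fixture(cols)
        mask = set(filter_blocks(a).tolist())
        left = {3 * j + k for j in range(12) for k in range(3)}
        run = {3 * j + k for j in range(12, 21) for k in range(3)}
        right = {3 * j + k for j in range(21, 33) for k in range(3)}
        assert left <= mask and right <= mask
        assert run.isdisjoint(mask)

    def test_eight_column_run_kept_inside_block(self):
        cols = ["AAAA"] * 12 + ["ACDE"] * 8 + ["AAAA"] * 12
        a = protein_alignment_fixture(cols)
        mask = set(filter_blocks(a).tolist())
        assert len(mask) == 3 * 32  # single block, run retained

    def test_short_block_dropped(self):
        cols = ["AAAA"] * 9 + ["ACDE"] * 9 + ["AAAA"] * 12
        a = protein_alignment_fixture(cols)
        mask = set(filter_blocks(a).tolist())
        left = {3 * j + k for j in range(9) for k in range(3)}
        assert left.isdisjoint(mask)  # 9 < minimum block length

    def test_mask_monotone_in_min_block_length(self):
        rng = random.Random(9)
        residues = "ACDEFGHIKL"
        cols = []
        for _ in range(80):
            if rng.random() < 0.6:
                cols.append(rng.choice(residues) * 4)
            else:
                cols.append("".join(rng.choice(residues) for _ in range(4)))
        a = protein_alignment_fixture(cols)
        prev = None
        for mbl in (5, 10, 20, 40):
            m = set(filter_blocks(a, min_block_len=mbl).tolist())
            if prev is not None:
                assert m <= prev
            prev = m


class TestApplyLedger:
    def make_inputs(self):
        rng = random.Random(3)
        members = {sp: [f"{sp}_g1"] for sp in REFERENCE_SPECIES}
        for sp in TARGET_SPECIES:
            members[sp] = [f"{sp}_t0"]
        g = OrthoGroup(group_id="g1", members=members)
        g.recompute()
        ref = {sp: {f"{sp}_g1": random_cds(rng, 40)} for sp in REFERENCE_SPECIES}
        transcripts = {"g1": [(f"{sp}_t0", random_cds(rng, 50)) for sp in TARGET_SPECIES]}
        return g, ref, transcripts

    def test_clean_group_yields_no_entries(self):
        g, ref, tr = self.make_inputs()
        assert apply_ledger([g], ref, tr) == []

    def test_internal_stop_detected_once(self):
        g, ref, tr = self.make_inputs()
        cds = ref["Oropetium"]["Oropetium_g1"]
        ref["Oropetium"]["Oropetium_g1"] = cds[:30] + "TAA" + cds[33:]
        entries = apply_ledger([g], ref, tr)
        assert [(e.group_id, e.reason) for e in entries] == [("g1", "internal_stop_reference")]

    def test_no_stop_transcript_detected(self):
        g, ref, tr = self.make_inputs()
        tid, seq = tr["g1"][0]
        tr["g1"][0] = (tid, seq.replace("T", "C"))
        entries = apply_ledger([g], ref, tr)
        assert [(e.group_id, e.reason) for e in entries] == [("g1", "no_stop_six_frames")]

    def test_missing_annotation_detected(self):
        g, ref, tr = self.make_inputs()
        del ref["Brachypodium"]["Brachypodium_g1"]
        entries = apply_ledger([g], ref, tr)
        assert [(e.group_id, e.reason) for e in entries] == [("g1", "missing_annotation")]
        assert discarded_group_ids(entries) == {"g1"}

    def test_short_alignment_flag_at_897nt(self):
        g, ref, tr = self.make_inputs()
        aln = CodonAlignment(rows={"A": "" }, protein_rows={"A": ""})
        aln.mask = np.arange(897)
        entries = apply_ledger([g], ref, tr, alignments={"g1": [aln]})
        assert [(e.group_id, e.reason) for e in entries] == [("g1", "short_alignment")]
        # short groups are flagged, not discarded from the all-genes analysis
        assert discarded_group_ids(entries) == set()

    def test_900nt_mask_not_flagged(self):
        g, ref, tr = self.make_inputs()
        aln = CodonAlignment(rows={"A": ""}, protein_rows={"A": ""})
        aln.mask = np.arange(900)
        assert apply_ledger([g], ref, tr, alignments={"g1": [aln]}) == []
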
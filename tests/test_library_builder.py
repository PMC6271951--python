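"""Combinatorial library construction: filtering, dedup, coupling, sampling."""

import itertools

import pytest

from oxascreen import chem_core as cc, library_builder as lb, synthetic_data as sd
from oxascreen.chem_core import fingerprint, heavy_atom_count, tanimoto


class TestFilterBlocks:
    def test_boundaries_inclusive(self, block):
        blocks = [
            block("CCCC", "b4"), block("CCCCCC", "b6"),
            block("CCCCCCCCCCCC", "b12"), block("CCCCCCCCCCCCC", "b13"),
        ]
        kept = lb.filter_blocks(blocks)
        assert [b.id for b in kept] == ["b6", "b12"]

    def test_empty_input(self):
        assert lb.filter_blocks([]) == []

    def test_known_composition(self, block):
        # 30 blocks below six heavy atoms, 70 within range
        blocks = [block("CCC", f"s{i}") for i in range(30)]
        blocks += [block("CCCCCCCC", f"l{i}") for i in range(70)]
        assert len(lb.filter_blocks(blocks)) == 70


class TestDedupeBySimilarity:
    def test_identical_molecules_collapse(self, block):
        blocks = [block("CCO", f"b{i}") for i in range(5)]
        assert len(lb.dedupe_by_similarity(blocks)) == 1

    def test_dissimilar_all_kept(self, block):
        blocks = [block(s, s) for s in ("CCCCCC", "c1ccccc1", "OCC(O)CO")]
        assert len(lb.dedupe_by_similarity(blocks)) == 3

    def test_planted_redundant_families_reduce_to_one_each(self):
        blocks = sd.generate_block_families(10, 5, seed=3, level="redundant")
        kept = lb.dedupe_by_similarity(blocks, threshold=0.95)
        assert len(kept) == 10
        # kept set is pairwise sub-threshold
        fps = [fingerprint(b.mol) for b in kept]
        for fa, fb in itertools.combinations(fps, 2):
            assert tanimoto(fa, fb) < 0.95

    def test_matches_exhaustive_greedy_oracle(self):
        blocks = sd.generate_block_families(6, 4, seed=11, level="redundant")
        fps = [fingerprint(b.mol) for b in blocks]
        kept_idx = []
        for i in range(len(blocks)):
            if all(tanimoto(fps[i], fps[j]) < 0.95 for j in kept_idx):
                kept_idx.append(i)
        expected = [blocks[i].id for i in kept_idx]
        assert [b.id for b in lb.dedupe_by_similarity(blocks, 0.95)] == expected

    def test_idempotent(self):
        blocks = sd.generate_block_families(5, 3, seed=7, level="redundant")
        once = lb.dedupe_by_similarity(blocks)
        assert lb.dedupe_by_similarity(once) == once


class TestAttachmentPoints:
    def test_methane_single_carbon(self):
        mol = cc.parse_molecule("C", "methane")
        assert lb.attachment_points(mol) == (0,)

    def test_benzene_all_six(self):
        mol = cc.parse_molecule("c1ccccc1", "bz")
        assert len(lb.attachment_points(mol)) == 6

    def test_acetyl_chloride_methyl_only(self):
        # carbonyl C has no H; Cl is not an attachable element
        mol = cc.parse_molecule("CC(=O)Cl", "acecl")
        points = lb.attachment_points(mol)
        assert len(points) == 1
        assert mol.rdkit_mol.GetAtomWithIdx(points[0]).GetSymbol() == "C"
        assert mol.rdkit_mol.GetAtomWithIdx(points[0]).GetTotalNumHs() == 3


class TestCoupleBlocks:
    def test_atom_count_conservation(self, scaffold, block):
        b1, b2 = block("CN", "b1"), block("CO", "b2")
        compound = lb.couple_blocks(
            scaffold, b1, b1.attachment_atoms[0], b2, b2.attachment_atoms[0]
        )
        expected = (
            heavy_atom_count(scaffold.mol)
            + heavy_atom_count(b1.mol)
            + heavy_atom_count(b2.mol)
        )
        assert heavy_atom_count(compound.assembled) == expected

    def test_dibenzylamide_topology(self, scaffold, block):
        benzyl = block("Cc1ccccc1", "bn")
        ap = next(
            i for i in benzyl.attachment_atoms
            if benzyl.mol.rdkit_mol.GetAtomWithIdx(i).GetTotalNumHs() == 3
        )
        compound = lb.couple_blocks(scaffold, benzyl, ap, benzyl, ap)
        expected = cc.parse_molecule(
            "Nc1ncc(C(=O)N(Cc2ccccc2)Cc2ccccc2)o1", "dibenzylamide"
        )
        assert compound.assembled.canonical_string == expected.canonical_string

    def test_budget_rejection(self, scaffold, block):
        b9 = block("CCCCCCCCC", "b9")
        b10 = block("CCCCCCCCCC", "b10")
        with pytest.raises(lb.BudgetExceededError, match="19"):
            lb.couple_blocks(scaffold, b9, 0, b10, 0)

    def test_invalid_attachment_atom(self, scaffold, block):
        b = block("CC(=O)Cl", "b")
        bad = next(
            i for i in range(heavy_atom_count(b.mol)) if i not in b.attachment_atoms
        )
        with pytest.raises(lb.CouplingError):
            lb.couple_blocks(scaffold, b, bad, b, b.attachment_atoms[0])

    def test_scaffold_substructure_retained(self, scaffold, block):
        b = block("CCN", "b")
        compound = lb.couple_blocks(scaffold, b, 0, b, 0)
        from rdkit import Chem

        core = Chem.MolFromSmiles("Nc1ncco1")
        assert compound.assembled.rdkit_mol.HasSubstructMatch(core)


class TestEnumerateLibrary:
    def test_single_block_self_pair(self, scaffold, block):
        b = block("CCCCCC", "01")
        b = lb.BuildingBlock(b.id, b.mol, (b.attachment_atoms[0],))
        lib = list(lb.enumerate_library(scaffold, [b]))
        assert len(lib) == 1
        assert lib[0].r1[0] == lib[0].r2[0] == "01"

    def test_three_blocks_single_site_gives_six(self, scaffold, single_site_blocks):
        lib = list(lb.enumerate_library(scaffold, single_site_blocks))
        assert len(lib) == 6  # 3 self-pairs + 3 cross-pairs

    def test_matches_bruteforce_site_pair_oracle(self, scaffold, block):
        blocks = [
            block("Cc1ccccc1", "01"), block("OCCCCC", "02"), block("CCNCC", "03"),
        ]
        sites = [
            (b, ap) for b in blocks for ap in b.attachment_atoms
        ]
        expected = set()
        for (b1, a1), (b2, a2) in itertools.combinations_with_replacement(sites, 2):
            if heavy_atom_count(b1.mol) + heavy_atom_count(b2.mol) > 18:
                continue
            c = lb.couple_blocks(scaffold, b1, a1, b2, a2)
            expected.add(c.assembled.canonical_string)
        lib = list(lb.enumerate_library(scaffold, blocks, dedupe_threshold=1.0000001))
        produced = {c.assembled.canonical_string for c in lib}
        # with dedup effectively off, the distinct products must coincide
        assert produced == expected

    def test_budget_respected_everywhere(self, scaffold, block):
        blocks = [block("CCCCCCCCC", "b9"), block("CCCCCCCCCC", "b10")]
        lib = list(lb.enumerate_library(scaffold, blocks, budget=18))
        for c in lib:
            assert c.r1[0] != "b10" or c.r2[0] != "b10"

    def test_coincident_products_removed(self, scaffold, single_site_blocks):
        # duplicating a block under a new id creates identical assemblies
        twin = lb.BuildingBlock(
            "99", single_site_blocks[0].mol, single_site_blocks[0].attachment_atoms
        )
        lib = list(
            lb.enumerate_library(scaffold, [single_site_blocks[0], twin])
        )
        strings = [c.assembled.canonical_string for c in lib]
        assert len(strings) == len(set(strings)) == 1


class TestSampleLibrary:
    def test_full_sample_is_whole_library(self, scaffold, single_site_blocks):
        lib = list(lb.enumerate_library(scaffold, single_site_blocks))
        sample = lb.sample_library(iter(lib), len(lib), seed=1)
        assert {c.identifier for c in sample} == {c.identifier for c in lib}

    def test_seed_determinism(self, scaffold, single_site_blocks):
        lib = list(lb.enumerate_library(scaffold, single_site_blocks))
        s1 = lb.sample_library(iter(lib), 3, seed=42)
        s2 = lb.sample_library(iter(lib), 3, seed=42)
        assert [c.identifier for c in s1] == [c.identifier for c in s2]

    def test_oversampling_rejected(self, scaffold, single_site_blocks):
        lib = list(lb.enumerate_library(scaffold, single_site_blocks))
        with pytest.raises(ValueError):
            lb.sample_library(iter(lib), len(lib) + 1, seed=0)

    def test_uniformity(self):
        # sampling 5 of 10 items: each should appear with frequency 1/2
        items = list(range(10))
        counts = dict.fromkeys(items, 0)
        reps = 2000
        for seed in range(reps):
            for x in lb.sample_library(iter(items), 5, seed=seed):
                counts[x] += 1
        for x in items:
            assert counts[x] / reps == pytest.approx(0.5, abs=0.05)


class TestCompoundIdentifier:
    @pytest.mark.parametrize(
        "r1,r2,combo,expected",
        [
            ("02168779", "40448781", 0, "ao-02168779-40448781-0000"),
            ("00403318", "01672846", 2, "ao-00403318-01672846-0002"),
        ],
    )
    def test_format(self, r1, r2, combo, expected):
        assert lb.compound_identifier_from_parts(r1, r2, combo) == expected

    def test_roundtrip(self):
        ident = lb.compound_identifier_from_parts("12345678", "87654321", 7)
        assert lb.parse_identifier(ident) == ("12345678", "87654321", 7)

    def test_three_digit_combination_accepted(self):
        assert lb.parse_identifier("ao-02168779-40448781-000") == (
            "02168779", "40448781", 0,
        )

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            lb.parse_identifier("zn-1-2-000")
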
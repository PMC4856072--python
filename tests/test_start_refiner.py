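"""Homology grouping, center-star alignment, and start-codon selection."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from mitocurate import (AnnotationTable, GeneAnnotation, Genome,
                        group_homologs, local_align, multi_align,
                        scan_orfs, select_start)
from mitocurate.orf_engine import Orf
from mitocurate.start_refiner import HomologGroup, local_score

from .oracles import gotoh_local_score

_B62 = substitution_matrices.load("BLOSUM62")
_AA = "ACDEFGHIKLMNPQRSTVWY"


class TestLocalAlign:
    def test_identical_sequences_score_diagonal_sum(self):
        score, (ra, rb) = local_align("MNSW", "MNSW")
        expected = sum(float(_B62[c, c]) for c in "MNSW")
        assert score == expected
        assert (ra, rb) == ("MNSW", "MNSW")

    def test_all_mismatch_pair_is_empty(self):
        score, pair = local_align("AAAA", "WWWW")
        assert score == 0.0 and pair == ("", "")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "MNSW")

    def test_unknown_residue_scored_as_x(self):
        # Biopython maps out-of-alphabet residues through our X substitution
        s1, _ = local_align("MUM", "MXM")
        s2, _ = local_align("MXM", "MXM")
        assert s1 == s2

    def test_matches_exhaustive_dp_oracle(self, rng):
        """Score equivalence with a full-matrix Gotoh DP on random pairs."""
        for _ in range(300):
            a = "".join(rng.choice(list(_AA), size=rng.integers(1, 31)))
            b = "".join(rng.choice(list(_AA), size=rng.integers(1, 31)))
            assert local_score(a, b) == gotoh_local_score(a, b), (a, b)


def _orf(protein, start=100, genome_id="g", cands=None):
    end = start + 3 * len(protein) - 1
    return Orf(genome_id=genome_id, frame=(start - 1) % 3, start=start,
               end=end, protein=protein, candidate_starts=cands or [])


class TestGroupHomologs:
    def test_panel_recovery_and_permutation_invariance(self, panel_truth):
        """All 12 ortholog groups recovered with one member per species,
        independent of species enumeration order."""
        truth = panel_truth
        orf_sets = {sp: scan_orfs(truth.genomes[sp]) for sp in truth.species}
        ref = truth.reference_proteins()
        groups = group_homologs(orf_sets, ref)
        by_gene = {g.gene: g for g in groups}
        assert set(by_gene) == set(ref)
        for gene, g in by_gene.items():
            assert sorted(g.members) == sorted(truth.species)
            for sp in truth.species:
                want, _ = truth.true_starts[(sp, gene)]
                assert g.members[sp].start == want
        reversed_sets = dict(reversed(list(orf_sets.items())))
        groups_r = group_homologs(reversed_sets, ref)
        assert {(g.gene, sp, g.members[sp].start)
                for g in groups for sp in g.members} == \
               {(g.gene, sp, g.members[sp].start)
                for g in groups_r for sp in g.members}

    def test_missing_gene_recorded_as_absence(self):
        ref = {"nad3": "MFNKYLVSLITSLMMNKW" * 6}
        orf_sets = {
            "a": [_orf(ref["nad3"])],
            "b": [_orf(ref["nad3"][:60] + "W" * 40)],
            "c": [],  # species lacking the gene entirely
        }
        (group,) = group_homologs(orf_sets, ref)
        assert sorted(group.members) == ["a", "b"]
        assert group.absences == ["c"]
        assert not group.unalignable

    def test_decoy_orf_below_threshold_unassigned(self):
        ref = {"nad3": "MFNKYLVSLITSLMMNKW" * 6}
        decoy = _orf("QQQQQQQQQQ")
        (group,) = group_homologs({"a": [decoy], "b": [decoy]}, ref)
        assert group.members == {}
        assert group.unalignable


class TestMultiAlign:
    def test_identical_pair_gapless_full_occupancy(self):
        g = HomologGroup(gene="x", members={"a": _orf("MNSWKL" * 10),
                                            "b": _orf("MNSWKL" * 10)})
        multi_align(g)
        rows = set(g.alignment.values())
        assert rows == {"MNSWKL" * 10}
        assert all(occ == 1.0 for occ in g.column_occupancy)

    def test_nterminal_extension_gets_low_occupancy_prefix(self):
        core = "MNSWKLIMNSWKLI" * 4
        g = HomologGroup(gene="x", members={
            "a": _orf("LLLLLLLLLL" + core),  # 10-aa N-terminal extension
            "b": _orf(core),
            "c": _orf(core),
        })
        multi_align(g)
        occ = g.column_occupancy
        assert occ[:10] == [1 / 3] * 10
        assert all(o == 1.0 for o in occ[10:])

    def test_occupancy_values_quantized_by_member_count(self, panel_truth):
        truth = panel_truth
        orf_sets = {sp: scan_orfs(truth.genomes[sp]) for sp in truth.species}
        groups = group_homologs(orf_sets, truth.reference_proteins())
        allowed = {0.25, 0.5, 0.75, 1.0}
        for g in groups[:4]:
            multi_align(g)
            assert set(g.column_occupancy) <= allowed


def _single_gene_setup(cands, gene_start, gene_len_nt, upstream_end,
                       genome_len=5000, species=("a", "b")):
    """Two-member group over the same coordinates with given candidates."""
    members = {}
    tables = {}
    protein = "MNSWKLI" * 20  # 140 aa
    for sp in species:
        orf = Orf(genome_id=sp, frame=(gene_start - 1) % 3,
                  start=gene_start, end=gene_start + gene_len_nt - 1,
                  protein=protein, candidate_starts=cands)
        members[sp] = orf
        table = AnnotationTable(genome_id=sp, features=[
            GeneAnnotation("trnA", "tRNA", upstream_end - 64, upstream_end),
            GeneAnnotation("x", "CDS", gene_start, gene_start + gene_len_nt - 1),
        ])
        table.genome_length = genome_len
        tables[sp] = table
    group = HomologGroup(gene="x", members=members)
    multi_align(group)
    return group, tables


class TestSelectStart:
    def test_planted_ttg_recovered_in_panel(self, panel_truth):
        """Full-pipeline start recovery on a panel with planted codons."""
        from mitocurate.start_refiner import refine_starts
        truth = panel_truth
        orf_sets = {sp: scan_orfs(truth.genomes[sp]) for sp in truth.species}
        calls = refine_starts(orf_sets, truth.reference_proteins(),
                              truth.tables)
        assert len(calls) == 12 * len(truth.species)
        for c in calls:
            pos, codon = truth.true_starts[(c.species, c.gene)]
            assert (c.position, c.codon) == (pos, codon), c

    def test_upstream_ttg_beats_downstream_atg_on_homology(self):
        """Conserved columns extend upstream of the ATG: TTG must win."""
        gene_start = 1000
        cands = [(gene_start, "TTG"), (gene_start + 180, "ATG")]
        group, tables = _single_gene_setup(cands, gene_start, 420,
                                           upstream_end=900)
        calls = select_start(group, tables)
        assert all(c.codon == "TTG" and c.position == gene_start
                   for c in calls)

    def test_atg_at_first_conserved_column_wins_tiebreak(self):
        gene_start = 1000
        cands = [(gene_start, "ATG"), (gene_start, "TTG")]
        group, tables = _single_gene_setup(cands, gene_start, 420,
                                           upstream_end=900)
        calls = select_start(group, tables)
        assert all(c.codon == "ATG" for c in calls)

    def test_overlap_penalty_rejects_candidate_inside_upstream_gene(self):
        """Equal conserved coverage, but the ATG overlaps the upstream
        feature by 30 bases: the overlap-free TTG is chosen."""
        gene_start = 1000
        upstream_end = gene_start + 29  # tRNA ends inside the ORF
        cands = [(gene_start, "ATG"), (gene_start + 30, "TTG")]
        members, tables = {}, {}
        protein = "X" * 10 + "MNSWKLI" * 20
        for sp in ("a", "b"):
            orf = Orf(genome_id=sp, frame=(gene_start - 1) % 3,
                      start=gene_start, end=gene_start + 3 * len(protein) - 1,
                      protein=protein, candidate_starts=cands)
            members[sp] = orf
            table = AnnotationTable(genome_id=sp, features=[
                GeneAnnotation("trnA", "tRNA", upstream_end - 64,
                               upstream_end),
                GeneAnnotation("x", "CDS", gene_start + 30,
                               gene_start + 3 * len(protein) - 1),
            ])
            table.genome_length = 5000
            tables[sp] = table
        group = HomologGroup(gene="x", members=members)
        multi_align(group)
        # the ATG covers 10 more conserved columns (150 vs 140) but pays a
        # 30-base overlap penalty: 150 - 30 = 120 < 140 - 0 = 140
        calls = select_start(group, tables)
        assert all(c.codon == "TTG" for c in calls)
        assert all(c.upstream_gap == 0 for c in calls)

    def test_member_without_candidates_is_skipped(self):
        gene_start = 1000
        group, tables = _single_gene_setup([(gene_start, "TTG")],
                                           gene_start, 420, upstream_end=900)
        group.members["b"].candidate_starts = []
        calls = select_start(group, tables)
        assert [c.species for c in calls] == ["a"]
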
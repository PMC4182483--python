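"""CMAD scoring, candidate filtering, local-structure emulation, combination
counting and template matching with pruning."""

import itertools

import numpy as np
import pytest

from xcmasa.config import SearchConfig
from xcmasa.errors import ValidationError
from xcmasa.fixtures import make_decoy, make_template, plant_site
from xcmasa.matching import (Base, LocalStructure, Simultaneous, Single,
                             Subtemplates, SubstitutionMatrix, cmad,
                             count_combinations, enumerate_local_structures,
                             filter_candidates, match_template,
                             postprocess_matches, search)
from xcmasa.structure_io import Identity, ResiduePoint, derive_residue_points
from xcmasa.templates import Template, TemplateLibrary, expand_library

THREE = {"E": "GLU", "D": "ASP", "K": "LYS", "H": "HIS"}


def _points(spec):
    """spec: list of (one_letter, ca_xyz) -> ResiduePoints with fa 1.5 A out."""
    pts = []
    for i, (one, ca) in enumerate(spec):
        ca = np.asarray(ca, float)
        pts.append(ResiduePoint(Identity("A", i + 1, "", THREE[one]),
                                ca, ca + np.array([0.0, 0.0, 1.5]), "XX"))
    return pts


def _template_of(points, types=None):
    residues = tuple(points)
    return Template(template_id="t", source_structure="t", family_id="t",
                    residues=residues)


class TestCmad:
    def test_identical_distance_sets_give_zero(self):
        assert cmad([3.0, 4.0, 5.0], [3.0, 4.0, 5.0]) == 0.0

    def test_three_pair_worked_value(self):
        # mean |difference| over the 3 pairs: (1 + 0 + 0)/3
        assert cmad([3.0, 4.0, 5.0], [4.0, 4.0, 5.0]) == pytest.approx(1 / 3)

    def test_symmetric_under_swap(self):
        a, b = [2.0, 7.5, 4.1], [2.2, 6.9, 4.4]
        assert cmad(a, b) == pytest.approx(cmad(b, a))

    def test_pair_count_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cmad([1.0, 2.0], [1.0, 2.0, 3.0])


class TestSubstitutionMatrix:
    def test_identity_diagonal(self):
        sm = SubstitutionMatrix.identity()
        assert sm.allows("E", "E") and not sm.allows("E", "H")

    def test_symmetry_of_added_pairs(self):
        sm = SubstitutionMatrix([("H", "E")])
        assert sm.allows("H", "E") and sm.allows("E", "H")

    def test_tsv_round_trip(self, tmp_path):
        sm = SubstitutionMatrix([("H", "E"), ("S", "T")])
        path = tmp_path / "sm.tsv"
        sm.write_tsv(path)
        back = SubstitutionMatrix.read_tsv(path)
        for a, b in itertools.product("ACDEFGHIKLMNPQRSTVWY", repeat=2):
            assert sm.allows(a, b) == back.allows(a, b)


# the worked query/template: residues E1,E2,D1,K1,K2,H1,H2 vs template (E,D,K)
QUERY_TYPES = ["E", "E", "D", "K", "K", "H", "H"]
QUERY_GEOM = _points([("E", (0, 0, 0)), ("E", (8, 0, 0)), ("D", (0, 6, 0)),
                      ("K", (4, 3, 2)), ("K", (9, 5, 1)), ("H", (2, 8, 3)),
                      ("H", (7, 7, 7))])
TEMPLATE_EDK = _template_of(_points([("E", (0, 0, 0)), ("D", (0, 6, 0)),
                                     ("K", (4, 3, 2))]))


class TestFilterCandidates:
    def test_identity_matrix_keeps_only_matching_types(self):
        slots = filter_candidates(QUERY_GEOM, TEMPLATE_EDK, None)
        names = [[p.identity.seq_number for p in s] for s in slots]
        assert names == [[1, 2], [3], [4, 5]]  # {E1,E2}, {D1}, {K1,K2}

    def test_sm_widens_the_substituted_slot(self):
        sm = SubstitutionMatrix([("H", "E")])
        slots = filter_candidates(QUERY_GEOM, TEMPLATE_EDK, sm)
        assert [p.identity.seq_number for p in slots[0]] == [1, 2, 6, 7]

    def test_absent_type_gives_empty_slot(self):
        q = _points([("E", (0, 0, 0)), ("K", (4, 3, 2))])
        slots = filter_candidates(q, TEMPLATE_EDK, None)
        assert slots[1] == []

    def test_fa_absent_residues_excluded(self):
        q = list(QUERY_GEOM)
        q[0] = ResiduePoint(q[0].identity, q[0].ca, None, None)
        slots = filter_candidates(q, TEMPLATE_EDK, None)
        assert [p.identity.seq_number for p in slots[0]] == [2]


class TestEnumerateLocalStructures:
    def test_worked_example_yields_four(self):
        slots = filter_candidates(QUERY_GEOM, TEMPLATE_EDK, None)
        out = list(enumerate_local_structures(slots, TEMPLATE_EDK))
        assert len(out) == 4
        assert all(isinstance(ls, LocalStructure) for ls in out)
        assert len({ls.correspondence for ls in out}) == 4

    def test_single_candidate_per_slot(self):
        q = _points([("E", (0, 0, 0)), ("D", (0, 6, 0)), ("K", (4, 3, 2))])
        slots = filter_candidates(q, TEMPLATE_EDK, None)
        assert len(list(enumerate_local_structures(slots, TEMPLATE_EDK))) == 1

    def test_counts_match_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(30):
            n = int(rng.integers(1, 5))
            pools = [[f"r{int(x)}" for x in
                      rng.choice(12, size=int(rng.integers(0, 7)), replace=False)]
                     for _ in range(n)]
            # oracle: product minus reuse, via brute force
            expect = sum(1 for combo in itertools.product(*pools)
                         if len(set(combo)) == len(combo))
            pts = {}
            slots = []
            for pool in pools:
                slot = []
                for rid in pool:
                    if rid not in pts:
                        idx = int(rid[1:])
                        ca = np.array([idx * 3.0, 0.0, 0.0])
                        pts[rid] = ResiduePoint(Identity("A", idx, "", "GLU"),
                                                ca, ca + 1.0, "XX")
                    slot.append(pts[rid])
                slots.append(slot)
            t = _template_of(_points([("E", (i * 3, 0, 0)) for i in range(max(n, 2))]))
            got = sum(1 for _ in enumerate_local_structures(slots, t))
            assert got == expect


class TestCountCombinations:
    def test_base_worked_example(self):
        assert count_combinations(QUERY_TYPES, "EDK", Base()) == 4

    @pytest.mark.parametrize("x,y,counting,expect", [
        ("H", "E", "total", 8),   # four Es to combine with one D and two Ks
        ("H", "D", "new", 8),
        ("H", "K", "new", 4),
    ])
    def test_single_substitution_scenarios(self, x, y, counting, expect):
        assert count_combinations(QUERY_TYPES, "EDK",
                                  Single(x, y, counting=counting)) == expect

    @pytest.mark.parametrize("targets,expect", [
        (("E", "D"), 2), (("E", "K"), 1), (("D", "K"), 2),
    ])
    def test_simultaneous_substitutions_unordered(self, targets, expect):
        assert count_combinations(QUERY_TYPES, "EDK",
                                  Simultaneous("H", targets)) == expect

    def test_subtemplate_contributions(self):
        # (E,D)=2, (E,K)=4, (D,K)=2 over the filtered query {E1,E2,D1,K1,K2}
        assert count_combinations(["E", "E", "D", "K", "K"], "EDK",
                                  Subtemplates(k=1)) == 8

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValidationError):
            count_combinations(QUERY_TYPES, "EDK", "bogus")
        with pytest.raises(ValidationError):
            count_combinations(QUERY_TYPES, "EDK", Single("H", "E", counting="huh"))


def _exhaustive_match(points, t, cutoff, sm=None):
    """Prune-free oracle: score every complete local structure, keep those
    whose CMADs both fall within the cutoff."""
    from xcmasa.matching import filter_candidates

    slots = filter_candidates(points, t, sm)
    n = t.n
    dt_ca = np.array([[np.linalg.norm(a.ca - b.ca) for b in t.residues]
                      for a in t.residues])
    dt_fa = np.array([[np.linalg.norm(a.fa - b.fa) for b in t.residues]
                      for a in t.residues])
    accepted = set()
    for combo in itertools.product(*slots):
        idents = [p.identity for p in combo]
        if len(set(idents)) != n:
            continue
        pairs = list(itertools.combinations(range(n), 2))
        d_ca = [abs(np.linalg.norm(combo[i].ca - combo[j].ca) - dt_ca[i, j])
                for i, j in pairs]
        d_fa = [abs(np.linalg.norm(combo[i].fa - combo[j].fa) - dt_fa[i, j])
                for i, j in pairs]
        if max(d_ca) <= cutoff and max(d_fa) <= cutoff:
            accepted.add(tuple(idents))
    return accepted


class TestMatchTemplate:
    def test_exact_planted_copy_scores_zero(self):
        decoy = make_decoy(40, seed=9)
        t = make_template("t", seed=9)
        planted, truth = plant_site(decoy, t, 0.0, seed=1)
        matches = match_template(derive_residue_points(planted), t, 0.4)
        exact = [m for m in matches if set(m.matched_residues) == set(truth)]
        assert len(exact) == 1
        m = exact[0]
        assert m.cmad_ca == pytest.approx(0.0, abs=1e-6)
        assert m.cmad_fa == pytest.approx(0.0, abs=1e-6)
        assert m.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_mutated_site_invisible_to_full_template(self):
        from xcmasa.structure_io import mutate_to_alanine

        decoy = make_decoy(40, seed=9)
        t = make_template("t", seed=9)
        planted, truth = plant_site(decoy, t, 0.0, seed=1)
        target = truth[0]
        mutated = mutate_to_alanine(planted, target.chain, target.seq_number,
                                    target.insertion_code)
        matches = match_template(derive_residue_points(mutated), t, 0.4)
        assert all(set(m.matched_residues) != {i for i in truth} for m in matches)

    def test_pruning_equals_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(17)
        for trial in range(25):
            n_q = int(rng.integers(8, 20))
            decoy = make_decoy(n_q, seed=int(rng.integers(2**31)))
            t = make_template("t", seed=int(rng.integers(2**31)),
                              site_size=int(rng.integers(2, 5)))
            pts = derive_residue_points(decoy)
            cutoff = float(rng.uniform(0.3, 2.5))
            got = {m.matched_residues for m in match_template(pts, t, cutoff)}
            assert got == _exhaustive_match(pts, t, cutoff)

    def test_cutoff_must_be_positive(self):
        t = make_template("t", seed=1)
        with pytest.raises(ValidationError):
            match_template([], t, 0.0)


class TestPostprocessMatches:
    def _mk(self, tid, parent, residues):
        from xcmasa.matching import MatchResult

        idents = tuple(Identity("A", i, "", "GLU") for i in residues)
        return MatchResult(template_id=tid, parent_template=parent,
                           matched_residues=idents, cmad_ca=0.0, cmad_fa=0.0,
                           rmsd=0.0, p_value=1e-9, is_subtemplate=parent is not None)

    def test_parent_subsumes_its_subtemplates(self):
        parent = self._mk("t", None, [1, 2, 3])
        sub = self._mk("t~minus-A3", "t", [1, 2])
        assert postprocess_matches([parent, sub]) == [parent]

    def test_orphan_subtemplate_match_retained(self):
        sub = self._mk("t~minus-A3", "t", [1, 2])
        assert postprocess_matches([sub]) == [sub]

    def test_subtemplate_on_different_residues_retained(self):
        parent = self._mk("t", None, [1, 2, 3])
        sub = self._mk("t~minus-A3", "t", [7, 8])  # not a subset of the parent's site
        assert postprocess_matches([parent, sub]) == [parent, sub]

    def test_empty_input(self):
        assert postprocess_matches([]) == []


class TestSearch:
    def test_empty_library_rejected(self):
        decoy = make_decoy(10, seed=1)
        with pytest.raises(ValidationError):
            search(decoy, TemplateLibrary([]))

    def test_planted_site_found_and_ranked_deterministically(self):
        decoy = make_decoy(60, seed=21)
        t = make_template("t", seed=21)
        planted, truth = plant_site(decoy, t, 0.0, seed=2)
        lib = expand_library(TemplateLibrary([t]))
        first = search(planted, lib)
        second = search(planted, lib)
        assert [(m.template_id, m.matched_residues) for m in first] == \
            [(m.template_id, m.matched_residues) for m in second]
        assert set(first[0].matched_residues) == set(truth)
        assert first[0].template_id == "t"  # parent subsumes subtemplate hits

    def test_mutant_recovered_via_subtemplate(self):
        from xcmasa.structure_io import mutate_to_alanine

        decoy = make_decoy(60, seed=22)
        t = make_template("t", seed=22)
        planted, truth = plant_site(decoy, t, 0.0, seed=3)
        target = next(i for i in truth if i.res_type not in ("GLY", "ALA"))
        mutated = mutate_to_alanine(planted, target.chain, target.seq_number,
                                    target.insertion_code)
        hits = search(mutated, expand_library(TemplateLibrary([t])))
        assert hits, "extended library should recover the non-mutated residues"
        top = hits[0]
        assert top.is_subtemplate and top.parent_template == "t"
        expect = {i[:3] for i in truth} - {target[:3]}
        assert {i[:3] for i in top.matched_residues} == expect

    def test_missing_fa_recovered_via_subtemplate(self):
        from xcmasa.fixtures import delete_side_chain

        decoy = make_decoy(60, seed=23)
        t = make_template("t", seed=23)
        planted, truth = plant_site(decoy, t, 0.0, seed=4)
        victim = truth[1]
        stripped = delete_side_chain(planted, victim)
        lib = expand_library(TemplateLibrary([t]))
        # full template cannot see the site...
        full_hits = [m for m in search(stripped, lib) if not m.is_subtemplate]
        assert all({i[:3] for i in m.matched_residues} != {i[:3] for i in truth}
                   for m in full_hits)
        # ...but the subtemplate omitting the stripped residue does
        hits = search(stripped, lib)
        expect = {i[:3] for i in truth} - {victim[:3]}
        assert any({i[:3] for i in m.matched_residues} == expect for m in hits)

    def test_subtemplate_dominance(self):
        # the best k=1 subtemplate never scores worse than its parent on the
        # induced sub-correspondence (a min of pair deviations vs their mean)
        from xcmasa.templates import subtemplates

        for seed in (31, 32, 33):
            decoy = make_decoy(50, seed=seed)
            t = make_template("t", seed=seed, site_size=4)
            planted, truth = plant_site(decoy, t, 0.15, seed=5)
            pts = derive_residue_points(planted)
            full = next(m for m in match_template(pts, t, 5.0)
                        if {i[:3] for i in m.matched_residues}
                        == {i[:3] for i in truth})
            best_ca, best_fa = [], []
            for i, sub in enumerate(subtemplates(t, k=1)):
                induced = tuple(r for j, r in enumerate(full.matched_residues)
                                if t.residues[j].identity
                                != sub.excluded_residues[0])
                hits = [m for m in match_template(pts, sub, 5.0)
                        if tuple(x[:3] for x in m.matched_residues)
                        == tuple(x[:3] for x in induced)]
                assert hits, "induced sub-correspondence must survive"
                best_ca.append(min(m.cmad_ca for m in hits))
                best_fa.append(min(m.cmad_fa for m in hits))
            assert min(best_ca) <= full.cmad_ca + 1e-9
            assert min(best_fa) <= full.cmad_fa + 1e-9
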
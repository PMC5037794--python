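import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from _oracles import brute_force_min_distance, brute_force_min_self_distance
from silkconform import structure as st
from silkconform.dqmas import DistanceRestraint
from silkconform.structure import (
    BETA_SHEET_TORSIONS,
    GEOMETRY,
    MODEL_SEQUENCE,
    SILK_I_STAR_CELL,
    SILK_I_STAR_TORSIONS,
    ComplexModel,
    RefinementParams,
    TorsionSet,
    UnitCell,
    build_chain,
    backbone_torsions,
    evaluate_restraints,
    glycerol_template,
    min_site_distance,
    pack_crystal,
    predicted_pairs,
    read_pdb,
    refine_complex,
    resolve_site,
    silk_crystal_scaffold,
    write_pdb,
)
from silkconform.synth import GlycPlacementParams, synth_complex_candidates


class TestChainBuilder:
    @pytest.mark.parametrize("torsions", [SILK_I_STAR_TORSIONS,
                                          BETA_SHEET_TORSIONS])
    def test_dihedral_round_trip(self, torsions):
        chain = build_chain("AG", torsions)
        rec = backbone_torsions(chain)
        for _, row in rec.iterrows():
            phi, psi = torsions.phi_psi("A" if row.res_name == "ALA" else "G")
            assert row.phi == pytest.approx(phi, abs=1e-4)
            assert row.psi == pytest.approx(psi, abs=1e-4)

    @given(hst.tuples(hst.floats(min_value=-179.0, max_value=180.0),
                      hst.floats(min_value=-179.0, max_value=180.0),
                      hst.floats(min_value=-179.0, max_value=180.0),
                      hst.floats(min_value=-179.0, max_value=180.0)))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_dihedral_round_trip_random_torsions(self, angles):
        pa, sa, pg, sg = angles
        ts = TorsionSet({"A": (pa, sa), "G": (pg, sg)})
        chain = build_chain("AGA", ts)
        rec = backbone_torsions(chain)
        for _, row in rec.iterrows():
            phi, psi = ts.phi_psi("A" if row.res_name == "ALA" else "G")
            assert row.phi == pytest.approx(phi, abs=1e-4)
            assert row.psi == pytest.approx(psi, abs=1e-4)

    def test_backbone_bond_lengths_match_geometry_table(self):
        chain = build_chain(MODEL_SEQUENCE)
        pos = {(int(r.res_id), r.atom_name): np.array([r.x, r.y, r.z])
               for r in chain.itertuples()}
        for i in range(1, 13):
            d_nca = np.linalg.norm(pos[(i, "CA")] - pos[(i, "N")])
            d_cac = np.linalg.norm(pos[(i, "C")] - pos[(i, "CA")])
            d_co = np.linalg.norm(pos[(i, "O")] - pos[(i, "C")])
            assert d_nca == pytest.approx(GEOMETRY["N-CA"], abs=1e-6)
            assert d_cac == pytest.approx(GEOMETRY["CA-C"], abs=1e-6)
            assert d_co == pytest.approx(GEOMETRY["C=O"], abs=1e-6)
            if i < 12:
                d_cn = np.linalg.norm(pos[(i + 1, "N")] - pos[(i, "C")])
                assert d_cn == pytest.approx(GEOMETRY["C-N"], abs=1e-6)

    def test_turn_form_more_compact_than_sheet(self):
        # the repeated type II beta-turn pulls Ca(i)..Ca(i+2) closer than
        # the extended beta-sheet conformation
        def mean_ca2(ts):
            chain = build_chain(MODEL_SEQUENCE, ts)
            ca = chain[chain.atom_name == "CA"][["x", "y", "z"]].to_numpy()
            return np.mean(np.linalg.norm(ca[2:] - ca[:-2], axis=1))

        assert mean_ca2(SILK_I_STAR_TORSIONS) < mean_ca2(BETA_SHEET_TORSIONS)

    def test_protons_present(self):
        chain = build_chain(MODEL_SEQUENCE)
        names = set(zip(chain.res_name, chain.atom_name))
        assert {("ALA", "HB1"), ("ALA", "HB2"), ("ALA", "HB3"),
                ("GLY", "HA2"), ("GLY", "HA3"), ("SER", "HG"),
                ("SER", "HB2"), ("ALA", "H")} <= names

    def test_unknown_residue_letter(self):
        with pytest.raises(ValueError, match="W"):
            build_chain("AWG")


class TestPackCrystal:
    def test_single_copy_identical_to_chain(self):
        chain = build_chain("AG")
        scaffold = pack_crystal(chain, SILK_I_STAR_CELL, (1, 1, 1))
        np.testing.assert_array_equal(scaffold.coords,
                                      chain[["x", "y", "z"]].to_numpy())

    def test_lattice_translation_along_a(self):
        chain = build_chain("AG")
        scaffold = pack_crystal(chain, SILK_I_STAR_CELL, (2, 1, 1))
        n = len(chain)
        first = scaffold.coords[:n]
        second = scaffold.coords[n:]
        shift = second - first
        np.testing.assert_allclose(shift, np.tile([4.65, 0, 0], (n, 1)),
                                   atol=1e-12)

    def test_atom_count_scales_with_copies(self):
        chain = build_chain("AGA")
        scaffold = pack_crystal(chain, SILK_I_STAR_CELL, (2, 2, 1))
        assert len(scaffold.atoms) == 4 * len(chain)

    def test_transform_count_mismatch(self):
        chain = build_chain("AG")
        with pytest.raises(ValueError, match="placements"):
            pack_crystal(chain, SILK_I_STAR_CELL, (2, 1, 1),
                         placements=[(np.eye(3), np.zeros(3))])

    def test_invalid_cell(self):
        with pytest.raises(ValueError):
            UnitCell(-1.0, 2.0, 3.0)
        with pytest.raises(ValueError):
            UnitCell(1.0, 2.0, 3.0, alpha=190.0)


class TestSiteDistances:
    def test_matches_brute_force_oracle(self, candidate_model):
        pairs = [("Glyc CH2", "Ala Hbeta"), ("Glyc OH", "Ser Halpha"),
                 ("Ala HN", "Gly HN"), ("Glyc OH", "Glyc CH2")]
        for a, b in pairs:
            fast = min_site_distance(candidate_model, a, b)
            slow = brute_force_min_distance(resolve_site(candidate_model, a),
                                            resolve_site(candidate_model, b))
            assert fast == slow

    def test_symmetric(self, candidate_model):
        assert min_site_distance(candidate_model, "Glyc OH", "Ala HN") == \
            min_site_distance(candidate_model, "Ala HN", "Glyc OH")

    def test_self_group_uses_distinct_instances(self, silkI_scaffold):
        d = min_site_distance(silkI_scaffold, "Ser Halpha", "Ser Halpha")
        slow = brute_force_min_self_distance(
            resolve_site(silkI_scaffold, "Ser Halpha"))
        assert d == slow

    def test_single_instance_self_distance_is_error(self):
        chain = build_chain("AGS")  # one Ser -> one Ser Halpha proton
        model = ComplexModel(chain)
        with pytest.raises(ValueError, match="single instance"):
            min_site_distance(model, "Ser Halpha", "Ser Halpha")

    def test_zero_atom_group_is_error(self, silkI_scaffold):
        with pytest.raises(ValueError, match="zero atoms"):
            min_site_distance(silkI_scaffold, "Glyc OH", "Ala HN")

    def test_distant_glycerols(self, silkI_scaffold):
        tmpl = glycerol_template()[["x", "y", "z"]].to_numpy()
        model = silkI_scaffold.with_glycerols([tmpl + [60, 0, 0],
                                               tmpl + [160, 0, 0]])
        assert min_site_distance(model, "Glyc CH2", "Glyc CH2") > 4.0


class TestPredictedPairs:
    def test_scaffold_contains_expected_contacts(self, silkI_scaffold):
        pairs = predicted_pairs(silkI_scaffold)
        assert tuple(sorted(("Ala Hbeta", "Ala HN"))) in pairs
        assert tuple(sorted(("Gly Halpha1", "Gly HN"))) in pairs

    def test_tiny_cutoff_empty(self, silkI_scaffold):
        assert predicted_pairs(silkI_scaffold, cutoff=0.1) == set()

    def test_invariant_under_atom_permutation(self, candidate_model):
        pairs = predicted_pairs(candidate_model)
        rng = np.random.default_rng(0)
        shuffled = candidate_model.atoms.sample(
            frac=1.0, random_state=12).reset_index(drop=True)
        permuted = ComplexModel(shuffled)
        assert predicted_pairs(permuted) == pairs

    def test_structure_to_spectrum_closure(self, silkI_scaffold, shift_table):
        # peaks synthesized from the scaffold's contact map assign back to
        # pairs inside that same contact map
        from silkconform.dqmas import assign_peaklist
        from silkconform.synth import synth_dq_peaklist

        contacts = predicted_pairs(silkI_scaffold)
        site_conf = {"Ala Hbeta": "silkI*", "Ala Halpha": "silkI*",
                     "Ala HN": "silkI*", "Gly Halpha1": "silkI*",
                     "Gly Halpha2": "silkI*", "Gly HN": "silkI*",
                     "Ser Halpha": "silkI*"}
        pairs = [((site_conf[a], a), (site_conf[b], b))
                 for a, b in contacts if a in site_conf and b in site_conf]
        peaks = synth_dq_peaklist(shift_table, pairs)
        assignments, unassigned = assign_peaklist(peaks, shift_table,
                                                  candidate_pairs=pairs,
                                                  tolerance=1e-9)
        recovered = {tuple(sorted((sa, sb)))
                     for (_, sa), (_, sb) in (a.pair for a in assignments)}
        assert recovered <= contacts
        assert not unassigned


class TestRestraintEvaluation:
    def test_all_satisfied_accepts(self, candidate_model, six_restraints):
        relaxed = [DistanceRestraint(r.group_a, r.group_b, 50.0)
                   for r in six_restraints]
        ev = evaluate_restraints(candidate_model, relaxed)
        assert ev.accepted and ev.records["satisfied"].all()

    def test_single_violation_flags_exactly_that_restraint(self,
                                                           candidate_model,
                                                           six_restraints):
        dists = {(r.group_a, r.group_b):
                 min_site_distance(candidate_model, r.group_a, r.group_b)
                 for r in six_restraints}
        tight_key = max(dists, key=dists.get)
        restraints = [
            DistanceRestraint(r.group_a, r.group_b,
                              dists[(r.group_a, r.group_b)] - 0.1
                              if (r.group_a, r.group_b) == tight_key
                              else 50.0)
            for r in six_restraints]
        ev = evaluate_restraints(candidate_model, restraints)
        assert not ev.accepted
        bad = ev.records[~ev.records["satisfied"]]
        assert len(bad) == 1
        assert (bad.iloc[0]["group_a"], bad.iloc[0]["group_b"]) == tight_key

    def test_empty_restraints_accept_with_warning(self, candidate_model):
        ev = evaluate_restraints(candidate_model, [])
        assert ev.accepted and ev.empty_warning

    def test_unresolvable_group_named(self, silkI_scaffold):
        with pytest.raises(ValueError, match="Glyc OH"):
            evaluate_restraints(silkI_scaffold,
                                [DistanceRestraint("Glyc OH", "Ala HN")])


class TestRefinement:
    def test_zero_moves_is_identity(self, candidate_model, six_restraints):
        out = refine_complex(candidate_model, six_restraints,
                             RefinementParams(max_moves=0))
        np.testing.assert_array_equal(out.coords, candidate_model.coords)

    def test_rigid_moves_preserve_glycerol_geometry(self, candidate_model,
                                                    six_restraints):
        from scipy.spatial.distance import pdist

        refined = refine_complex(candidate_model, six_restraints,
                                 RefinementParams(max_moves=500, seed=2))
        for rid in candidate_model.glyc_res_ids():
            idx = candidate_model.glyc_indices(rid)
            before = pdist(candidate_model.coords[idx])
            after = pdist(refined.coords[idx])
            np.testing.assert_allclose(after, before, atol=1e-9)

    def test_never_increases_violations(self, silkI_scaffold, six_restraints):
        cand = synth_complex_candidates(
            silkI_scaffold, GlycPlacementParams(n_candidates=1,
                                                n_glyc_per_model=4,
                                                seed=21))[0]
        before = evaluate_restraints(cand, six_restraints).n_violated()
        refined = refine_complex(cand, six_restraints,
                                 RefinementParams(max_moves=300, seed=4))
        after = evaluate_restraints(refined, six_restraints).n_violated()
        assert after <= before

    def test_distant_candidate_refines_to_acceptance(self, silkI_scaffold,
                                                     six_restraints):
        # all six restrained distances start in [6, 10] A; the default-
        # schedule annealing must close them for >= 8 of 10 seeds
        cand = synth_complex_candidates(
            silkI_scaffold, GlycPlacementParams(n_candidates=1,
                                                n_glyc_per_model=8,
                                                shell_min=6.0, shell_max=10.0,
                                                seed=3))[0]
        dists = evaluate_restraints(cand, six_restraints).records["distance"]
        assert (dists > 4.0).all()
        accepted = 0
        clash_free = True
        for seed in range(10):
            refined = refine_complex(cand, six_restraints,
                                     RefinementParams(max_moves=4000,
                                                      seed=seed))
            ev = evaluate_restraints(refined, six_restraints)
            if ev.accepted:
                accepted += 1
                sf = refined.sf_coords()
                for rid in refined.glyc_res_ids():
                    g = refined.coords[refined.glyc_indices(rid)]
                    if brute_force_min_distance(g, sf) < 2.2 - 1e-9:
                        clash_free = False
        assert accepted >= 8
        assert clash_free

    def test_no_glycerols_is_error(self, silkI_scaffold, six_restraints):
        with pytest.raises(ValueError, match="glycerol"):
            refine_complex(silkI_scaffold, six_restraints)


class TestPdbIO:
    def test_round_trip_preserves_coordinates(self, candidate_model,
                                              tmp_path):
        path = tmp_path / "model.pdb"
        write_pdb(candidate_model, path)
        back = read_pdb(path)[0]
        np.testing.assert_allclose(back.coords, candidate_model.coords,
                                   atol=1e-3)
        assert (back.atoms.loc[back.atoms.res_name == "GOL", "mol"]
                == "GLYC").all()

    def test_cryst1_carries_unit_cell(self, silkI_scaffold, tmp_path):
        path = tmp_path / "scaffold.pdb"
        write_pdb(silkI_scaffold, path)
        line = next(l for l in path.read_text().splitlines()
                    if l.startswith("CRYST1"))
        assert "4.650" in line and "14.240" in line and "8.880" in line
        back = read_pdb(path)[0]
        assert back.cell.a == pytest.approx(4.65, abs=1e-3)

    def test_multi_model_candidate_set(self, silkI_scaffold, tmp_path):
        models = synth_complex_candidates(
            silkI_scaffold, GlycPlacementParams(n_candidates=3,
                                                n_glyc_per_model=2, seed=1))
        path = tmp_path / "set.pdb"
        write_pdb(models, path)
        assert path.read_text().count("\nMODEL") + 1 >= 3
        back = read_pdb(path)
        assert len(back) == 3
        np.testing.assert_allclose(back[2].coords, models[2].coords,
                                   atol=1e-3)

    def test_malformed_record_reports_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("ATOM      1  N   ALA A   1      bad      0.0     "
                        "0.0  1.00  0.00           N\n")
        with pytest.raises(ValueError, match="line 1"):
            read_pdb(path)
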
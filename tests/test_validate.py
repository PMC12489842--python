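"""Productive-complex checklist: coordination, motifs, waters, nucleoside
geometry and binding-mode classification."""

from __future__ import annotations

import numpy as np
import pytest

from substrate_graft import (
    CanonicalReference,
    FixtureSpec,
    Selector,
    apply_transform,
    base_plane_angle,
    check_bidentate,
    classify_binding_mode,
    detect_hbonds,
    dxg_distances,
    find_dxg_motifs,
    glycosidic_chi,
    graft_complex,
    hydration_shell_count,
    identify_components,
    make_ideal_nucleotide,
    make_toy_complex,
    ribose_pucker,
    select_atoms,
    steric_clashes,
    superpose_structures,
    validate_closed_state,
)
from substrate_graft.errors import AnnotationError, DataError, InputError
from substrate_graft.fixtures import rotate_base
from substrate_graft.geometry import rotation_about_axis
from substrate_graft.ligands import NucleotideLigand
from substrate_graft.structures import Atom, Residue, Structure
from substrate_graft.superpose import RigidTransform
from substrate_graft.validate import (
    classify_pucker,
    pseudorotation_from_torsions,
    ring_torsions,
)


def _rigid() -> RigidTransform:
    return RigidTransform(rotation_about_axis([2, 5, 1], 47.0),
                          np.array([3.0, -7.0, 2.0]))


class TestBidentate:
    def test_planted_coordination_is_bidentate(self, toy_complex):
        report = check_bidentate(toy_complex)
        assert report.bidentate
        assert len(report.groups) >= 2

    def test_distant_cofactor_is_not_bidentate(self, toy_complex):
        far = toy_complex.copy()
        far.chains["M"][0].atoms[0].coord = np.array([50.0, 50.0, 50.0])
        assert not check_bidentate(far).bidentate

    def test_two_oxygens_on_same_phosphate_group_do_not_count(self):
        ligand = make_ideal_nucleotide("ATP", analog=True)
        o1g, o2g = ligand.get("O1G").coord, ligand.get("O2G").coord
        # cofactor on the perpendicular bisector of the two gamma oxygens,
        # 2.5 A from each and away from the beta group
        midpoint = 0.5 * (o1g + o2g)
        u = o2g - o1g
        s = np.linalg.norm(u)
        u /= s
        w = midpoint - ligand.get("PB").coord
        w -= np.dot(w, u) * u
        w /= np.linalg.norm(w)
        offset = midpoint + np.sqrt(2.5 ** 2 - (s / 2.0) ** 2) * w
        st = Structure("samegroup", {
            "L": [ligand.to_residue()],
            "M": [Residue("CA", 1, "", [Atom("CA", "CA", offset)])],
        })
        report = check_bidentate(st)
        assert np.linalg.norm(o1g - offset) == pytest.approx(2.5, abs=1e-9)
        assert np.linalg.norm(o2g - offset) == pytest.approx(2.5, abs=1e-9)
        assert report.groups == ["G"]
        assert not report.bidentate

    def test_missing_cofactor_is_input_error(self, toy_complex):
        no_metal = select_atoms(toy_complex, Selector(chains=["A", "L", "W"]))
        with pytest.raises(InputError):
            check_bidentate(no_metal)


class TestDxgMotifs:
    def test_two_aspartates_found_in_sequence_order(self, toy_complex):
        _, cofactor, _ = identify_components(toy_complex)
        motifs = find_dxg_motifs(toy_complex, cofactor)
        asp1, asp2 = motifs.dxg_asp
        assert asp1.comp_id == asp2.comp_id == "ASP"
        assert asp1.seq_id < asp2.seq_id

    def test_single_candidate_is_annotation_error(self, toy_complex):
        _, cofactor, _ = identify_components(toy_complex)
        # mutate the second motif's glycine away
        broken = toy_complex.copy()
        for res in broken.chains["A"]:
            if res.comp_id == "GLY" and res.seq_id > 20:
                res.comp_id = "ALA"
        with pytest.raises(AnnotationError):
            find_dxg_motifs(broken, cofactor)

    def test_manual_override_skips_pattern_search(self, toy_complex):
        _, cofactor, _ = identify_components(toy_complex)
        broken = toy_complex.copy()
        for res in broken.chains["A"]:
            if res.comp_id == "GLY":
                res.comp_id = "ALA"
        motifs = find_dxg_motifs(broken, cofactor, override=(4, 24))
        assert {r.seq_id for r in motifs.dxg_asp} == {4, 24}

    def test_planted_distances_recovered_exactly(self, toy_complex):
        _, cofactor, _ = identify_components(toy_complex)
        motifs = find_dxg_motifs(toy_complex, cofactor)
        d1, d2 = dxg_distances(toy_complex, motifs, cofactor)
        assert d1 == pytest.approx(4.80, abs=1e-6)
        assert d2 == pytest.approx(4.84, abs=1e-6)

    def test_distances_invariant_under_rigid_motion(self, toy_complex):
        moved = apply_transform(toy_complex, _rigid())
        _, cofactor, _ = identify_components(moved)
        motifs = find_dxg_motifs(moved, cofactor)
        d1, d2 = dxg_distances(moved, motifs, cofactor)
        assert (d1, d2) == (pytest.approx(4.80, abs=1e-8),
                            pytest.approx(4.84, abs=1e-8))


class TestHydrationShell:
    def test_planted_shell_counts_four(self, toy_complex):
        _, cofactor, _ = identify_components(toy_complex)
        count, _ = hydration_shell_count(toy_complex, cofactor, cutoff=3.2)
        assert count == 4

    def test_zero_cutoff_counts_nothing(self, toy_complex):
        _, cofactor, _ = identify_components(toy_complex)
        assert hydration_shell_count(toy_complex, cofactor, cutoff=0.0)[0] == 0

    def test_count_monotone_in_cutoff(self, toy_complex):
        _, cofactor, _ = identify_components(toy_complex)
        counts = [hydration_shell_count(toy_complex, cofactor, cutoff=c)[0]
                  for c in (0.0, 2.0, 2.5, 3.2, 5.0, 10.0)]
        assert counts == sorted(counts)


class TestContacts:
    @staticmethod
    def _two_atom_structure(distance: float):
        return Structure("pair", {
            "A": [Residue("SER", 1, "", [Atom("OG", "O", np.zeros(3))]),
                  Residue("LYS", 3, "", [Atom("NZ", "N",
                                              np.array([distance, 0.0, 0.0]))])],
        })

    def test_o_to_n_at_hbond_distance_detected(self):
        contacts = detect_hbonds(self._two_atom_structure(2.8))
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(2.8)

    def test_pair_beyond_cutoff_is_empty(self):
        assert detect_hbonds(self._two_atom_structure(4.0), d_max=3.5) == []

    def test_grafted_complex_has_phosphate_contacts(self, toy_complex):
        contacts = detect_hbonds(toy_complex)
        assert contacts  # water network around the site at minimum

    def test_two_carbons_at_one_angstrom_clash(self):
        st = Structure("clash", {
            "A": [Residue("ALA", 1, "", [Atom("CB", "C", np.zeros(3))]),
                  Residue("ALA", 5, "", [Atom("CB", "C",
                                              np.array([1.0, 0.0, 0.0]))])],
        })
        clashes = steric_clashes(st, overlap_factor=0.6)
        assert len(clashes) == 1
        assert clashes[0].limit == pytest.approx(0.6 * 3.4)

    def test_self_graft_is_clash_free(self, toy_complex, toy_protein):
        substrate, cofactor, waters = identify_components(toy_complex)
        sup = superpose_structures(toy_complex, toy_protein)
        grafted = graft_complex(toy_protein, toy_complex, sup,
                                substrate=substrate, cofactor=cofactor,
                                waters=waters)
        assert steric_clashes(grafted, overlap_factor=0.6) == []

    def test_clash_count_monotone_in_overlap_factor(self, toy_complex):
        counts = [len(steric_clashes(toy_complex, overlap_factor=f))
                  for f in (0.4, 0.6, 0.8, 1.0)]
        assert counts == sorted(counts)

    def test_contact_results_invariant_under_atom_permutation(self, toy_complex):
        shuffled = toy_complex.copy()
        for _, res in shuffled.residues():
            res.atoms = list(reversed(res.atoms))
        assert len(steric_clashes(toy_complex)) == len(steric_clashes(shuffled))
        assert len(detect_hbonds(toy_complex)) == len(detect_hbonds(shuffled))


class TestPucker:
    @pytest.mark.parametrize("target, expected_cls", [
        (162.0, "C2'-endo"), (18.0, "C3'-endo"), (90.0, "other"),
        (270.0, "other"), (0.0, "C3'-endo"),
    ])
    def test_constructed_phase_classified(self, target, expected_cls):
        ligand = make_ideal_nucleotide("ATP", P=target)
        result = ribose_pucker(ligand)
        assert abs((result.P - target + 180.0) % 360.0 - 180.0) < 2.0
        assert result.cls == expected_cls

    def test_missing_ring_atom_is_data_error(self, atp_analog):
        broken = atp_analog.copy()
        broken.atoms = [a for a in broken.atoms if a.name != "O4'"]
        with pytest.raises(DataError):
            ribose_pucker(broken)

    def test_formula_matches_brute_force_cosine_fit(self, rng):
        """Closed-form pseudorotation phase vs a 0.01-degree grid search
        least-squares fit of the cosine model, over 1,000 random rings."""
        from substrate_graft.fixtures import _ring_from_phase

        n_rings = 1000
        phases = rng.uniform(0.0, 360.0, n_rings)
        amps = rng.uniform(0.15, 0.45, n_rings)
        grid = np.arange(0.0, 360.0, 0.01)
        cosines = np.cos(np.radians(
            grid[:, None] + 144.0 * (np.arange(5)[None, :] - 2)))  # (G, 5)
        denom = np.sum(cosines ** 2, axis=1)                       # (G,)
        nus = []
        for phi, q in zip(phases, amps):
            ring = _ring_from_phase(phi, q)
            ligand = NucleotideLigand("ATP", [
                Atom(name, name[0], ring[name]) for name in ring])
            nus.append(ring_torsions(ligand))
        nus = np.array(nus)                                        # (N, 5)
        closed_form = np.array([pseudorotation_from_torsions(nu)[0]
                                for nu in nus])
        for start in range(0, n_rings, 50):
            chunk = nus[start:start + 50]
            tau = np.maximum(chunk @ cosines.T / denom, 0.0)       # (n, G)
            resid = ((tau[:, :, None] * cosines[None, :, :]
                      - chunk[:, None, :]) ** 2).sum(axis=2)
            brute = grid[np.argmin(resid, axis=1)]
            diff = np.abs((closed_form[start:start + 50] - brute + 180.0)
                          % 360.0 - 180.0)
            assert np.max(diff) < 0.1

    def test_window_classification_boundaries(self):
        assert classify_pucker(0.0) == "C3'-endo"
        assert classify_pucker(35.99) == "C3'-endo"
        assert classify_pucker(36.0) == "other"
        assert classify_pucker(144.0) == "C2'-endo"
        assert classify_pucker(179.99) == "C2'-endo"
        assert classify_pucker(180.0) == "other"


class TestChi:
    @pytest.mark.parametrize("chi, expected", [
        (-120.0, "anti"), (170.0, "anti"), (95.0, "anti"),
        (60.0, "syn"), (-60.0, "syn"), (0.0, "syn"),
    ])
    def test_constructed_chi_classified(self, chi, expected):
        for kind in ("ATP", "UTP"):
            ligand = make_ideal_nucleotide(kind, chi=chi)
            result = glycosidic_chi(ligand)
            assert result.chi == pytest.approx(chi, abs=2.0)
            assert result.cls == expected

    def test_reference_substrate_is_anti(self, toy_components):
        substrate, _, _ = toy_components
        assert glycosidic_chi(substrate).cls == "anti"

    def test_missing_glycosidic_atoms_raise(self, atp_analog):
        broken = atp_analog.copy()
        broken.atoms = [a for a in broken.atoms if a.name != "N9"]
        with pytest.raises(DataError):
            glycosidic_chi(broken)


class TestBasePlaneAngle:
    def test_self_angle_zero(self, atp_analog):
        assert base_plane_angle(atp_analog, atp_analog) == pytest.approx(0.0,
                                                                         abs=1e-9)

    @pytest.mark.parametrize("angle", [30.0, 60.0, 90.0])
    def test_in_plane_axis_rotation_measured_exactly(self, atp_analog, angle):
        rotated = rotate_base(atp_analog, angle)
        assert base_plane_angle(atp_analog, rotated) == pytest.approx(angle,
                                                                      abs=1e-6)

    def test_folded_into_first_quadrant(self, atp_analog):
        rotated = rotate_base(atp_analog, 150.0)
        assert base_plane_angle(atp_analog, rotated) == pytest.approx(30.0,
                                                                      abs=1e-6)


class TestClassification:
    @pytest.fixture()
    def references(self, toy_components, adp_analog):
        substrate, _, _ = toy_components
        return CanonicalReference(ntp_reference=substrate,
                                  ndp_reference=adp_analog)

    def _self_graft(self, toy_complex, toy_protein):
        substrate, cofactor, waters = identify_components(toy_complex)
        sup = superpose_structures(toy_complex, toy_protein)
        return graft_complex(toy_protein, toy_complex, sup,
                             substrate=substrate, cofactor=cofactor,
                             waters=waters)

    def test_self_graft_is_canonical_with_zero_rmsd(self, toy_complex,
                                                    toy_protein, references):
        grafted = self._self_graft(toy_complex, toy_protein)
        report = classify_binding_mode(grafted, references)
        assert report.mode == "canonical"
        assert report.substrate_rmsd_vs_reference == pytest.approx(0.0,
                                                                   abs=1e-9)
        assert report.bidentate.bidentate
        assert report.shell_water_count == 4
        assert report.catalytic_water_present
        assert report.terminal_water_present
        assert report.dxg_distances == (pytest.approx(4.80, abs=1e-6),
                                        pytest.approx(4.84, abs=1e-6))
        assert report.pucker.cls == "C2'-endo"
        assert report.chi.cls == "anti"
        assert report.clashes == []

    def test_rotated_base_with_displaced_tail_is_alternative(
            self, toy_complex, toy_protein, references):
        # emulate the alternative pose: the nucleobase swings ~90 degrees
        # away and the whole nucleotide shifts, so the tail still aligns
        # within the permissive bound while the full-atom fit fails
        grafted = self._self_graft(toy_complex, toy_protein)
        shift = RigidTransform(np.eye(3), np.array([0.0, 1.3, 0.0]))
        grafted.substrate = rotate_base(
            grafted.substrate.transformed(shift), 90.0)
        report = classify_binding_mode(grafted, references)
        assert report.mode == "alternative"
        assert report.phosphate_ribose_rmsd == pytest.approx(1.3, abs=1e-9)
        assert report.base_plane_angle_vs_reference == pytest.approx(90.0,
                                                                     abs=1e-6)

    def test_displaced_substrate_is_nonproductive(self, toy_complex,
                                                  toy_protein, references):
        grafted = self._self_graft(toy_complex, toy_protein)
        shift = RigidTransform(np.eye(3), np.array([4.0, 4.0, 0.0]))
        grafted.substrate = grafted.substrate.transformed(shift)
        report = classify_binding_mode(grafted, references)
        assert report.mode == "nonproductive"

    def test_phosphate_count_mismatch_is_input_error(self, toy_complex,
                                                     toy_protein, references):
        grafted = self._self_graft(toy_complex, toy_protein)
        grafted.substrate.atoms = [a for a in grafted.substrate.atoms
                                   if not a.name.endswith("G") or
                                   a.element.upper() != "P"]
        # now 2 phosphorus atoms -> NDP reference (different base class is
        # fine); removing all phosphorus leaves nothing to match
        grafted.substrate.atoms = [a for a in grafted.substrate.atoms
                                   if a.element.upper() != "P"]
        with pytest.raises(InputError):
            classify_binding_mode(grafted, references)

    def test_report_isometry_invariance(self, toy_complex, toy_protein,
                                        references):
        grafted = self._self_graft(toy_complex, toy_protein)
        transform = _rigid()
        moved = graft_complex(
            apply_transform(toy_protein, transform),
            apply_transform(toy_complex, transform),
            superpose_structures(apply_transform(toy_complex, transform),
                                 apply_transform(toy_protein, transform)),
            *identify_components(apply_transform(toy_complex, transform)))
        moved_refs = CanonicalReference(
            ntp_reference=references.ntp_reference.transformed(transform),
            ndp_reference=references.ndp_reference.transformed(transform))
        a = classify_binding_mode(grafted, references)
        b = classify_binding_mode(moved, moved_refs)
        assert a.mode == b.mode
        assert a.substrate_rmsd_vs_reference == pytest.approx(
            b.substrate_rmsd_vs_reference, abs=1e-8)
        assert a.dxg_distances == (pytest.approx(b.dxg_distances[0], abs=1e-8),
                                   pytest.approx(b.dxg_distances[1], abs=1e-8))
        assert a.shell_water_count == b.shell_water_count
        assert a.pucker.P == pytest.approx(b.pucker.P, abs=1e-6)
        assert a.chi.chi == pytest.approx(b.chi.chi, abs=1e-6)


class TestClosedState:
    def test_template_against_itself_is_closed(self, toy_complex):
        report = validate_closed_state(toy_complex, toy_complex)
        assert report.ca_rmsd < 1e-9
        assert report.closed
        assert report.asp_asp_distance == pytest.approx(
            report.template_asp_asp_distance, abs=1e-9)

    def test_opened_domain_flagged(self, toy_complex):
        opened = toy_complex.copy()
        for res in opened.chains["A"]:
            if res.seq_id >= 21:   # second helix = the ACR4-bearing domain
                for atom in res.atoms:
                    atom.coord = atom.coord + np.array([0.0, 0.0, 8.0])
        report = validate_closed_state(opened, toy_complex)
        assert not report.closed
        assert report.asp_asp_distance > \
            report.template_asp_asp_distance + report.margin

    def test_model_matching_template_distance_is_closed(self, toy_complex):
        moved = apply_transform(
            select_atoms(toy_complex, Selector(category="polymer")), _rigid())
        report = validate_closed_state(moved, toy_complex)
        assert report.closed
        assert report.ca_rmsd < 1e-6
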
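import math

import numpy as np
import pytest

from igfab.electrostatics import (COULOMB_KJ_A, MODEL_PKA, LN10,
                                  IonizableSite, SolventModel,
                                  TooManySitesError, charge_folding_energy,
                                  dimer_charge_energy, enumerate_titration,
                                  extract_ionizable_sites, interaction_matrix,
                                  mc_titration, pair_energy)
from igfab._pdb import parse_structure
from igfab.synthetic import generate_toy_structure, toy_dimer_pdbs

from conftest import make_site, random_site_system


class TestPairEnergy:
    def test_unscreened_coulomb_closed_form(self, solvent_no_salt):
        i = make_site("Asp", (0, 0, 0))
        j = make_site("Lys", (10, 0, 0))
        w = pair_energy(i, j, solvent_no_salt)
        assert w == pytest.approx(COULOMB_KJ_A / (78.4 * 10.0), rel=1e-9)
        assert solvent_no_salt.kappa == 0.0

    def test_symmetry(self, solvent):
        rng = np.random.default_rng(0)
        for _ in range(20):
            i = make_site("Glu", rng.uniform(0, 20, 3))
            j = make_site("Arg", rng.uniform(0, 20, 3))
            assert pair_energy(i, j, solvent) == pair_energy(j, i, solvent)

    def test_screening_kills_interaction(self):
        i, j = make_site("Asp", (0, 0, 0)), make_site("Lys", (10, 0, 0))
        strong = SolventModel(ionic_strength=5.0)
        weak = SolventModel(ionic_strength=0.01)
        assert pair_energy(i, j, strong) < 1e-2 * pair_energy(i, j, weak)

    def test_distance_monotonicity(self, solvent):
        i = make_site("Asp", (0, 0, 0))
        near = pair_energy(i, make_site("Lys", (5, 0, 0)), solvent)
        far = pair_energy(i, make_site("Lys", (10, 0, 0)), solvent)
        assert abs(far) < abs(near)

    def test_coincident_sites_rejected(self, solvent):
        i = make_site("Asp", (0, 0, 0))
        j = make_site("Lys", (0, 0, 0))
        with pytest.raises(ValueError, match="coincident"):
            pair_energy(i, j, solvent)

    def test_close_contact_clamped(self, solvent):
        i = make_site("Asp", (0, 0, 0))
        at_clamp = pair_energy(i, make_site("Lys", (2.0, 0, 0)), solvent)
        below = pair_energy(i, make_site("Lys", (0.5, 0, 0)), solvent)
        assert below == pytest.approx(at_clamp)


class TestExactEnumeration:
    def test_single_site_henderson_hasselbalch(self, solvent):
        site = make_site("Asp", (0, 0, 0))
        res = enumerate_titration([site], solvent,
                                  ph_grid=np.array([4.0]), dg_ph=4.0)
        assert res.mean_protonation[0, 0] == pytest.approx(0.5)
        assert res.dg_charge == pytest.approx(0.0, abs=1e-12)

    def test_noninteracting_sites_factorise(self, solvent):
        sites = [make_site("Asp", (0, 0, 0)), make_site("Lys", (500, 0, 0))]
        grid = np.arange(2.0, 12.0, 0.5)
        res = enumerate_titration(sites, solvent, ph_grid=grid)
        for k, site in enumerate(sites):
            hh = 1.0 / (1.0 + 10.0 ** (grid - site.model_pKa))
            np.testing.assert_allclose(res.mean_protonation[k], hh, atol=1e-6)
        assert res.dg_charge == pytest.approx(0.0, abs=1e-9)

    def test_four_state_hand_oracle(self, solvent):
        """Asp + Lys at fixed W checked against an explicit 4-state sum."""
        asp = make_site("Asp", (0, 0, 0))
        lys = make_site("Lys", (4, 0, 0))
        W = interaction_matrix([asp, lys], solvent)[0, 1]
        RT = solvent.RT
        ph = 7.0
        # states (pa, pl); q_asp = pa - 1, q_lys = pl
        z_terms = {}
        for pa in (0, 1):
            for pl in (0, 1):
                e_self = LN10 * RT * ((ph - 4.0) * pa + (ph - 10.4) * pl)
                e_int = W * (pa - 1) * pl
                z_terms[(pa, pl)] = math.exp(-(e_self + e_int) / RT)
        z = sum(z_terms.values())
        z_free = sum(math.exp(-LN10 * ((ph - 4.0) * pa + (ph - 10.4) * pl))
                     for pa in (0, 1) for pl in (0, 1))
        dg_expected = -RT * math.log(z / z_free)
        theta_asp = (z_terms[(1, 0)] + z_terms[(1, 1)]) / z
        theta_lys = (z_terms[(0, 1)] + z_terms[(1, 1)]) / z

        res = enumerate_titration([asp, lys], solvent, ph_grid=np.array([7.0]))
        assert res.dg_charge == pytest.approx(dg_expected, rel=1e-9)
        assert res.mean_protonation[0, 0] == pytest.approx(theta_asp, rel=1e-9)
        assert res.mean_protonation[1, 0] == pytest.approx(theta_lys, rel=1e-9)

    def test_pka_shift_sign_for_salt_bridge(self, solvent, salt_bridge_sites):
        res = enumerate_titration(salt_bridge_sites, solvent)
        asp_pka, lys_pka = res.pkas
        assert asp_pka < MODEL_PKA["Asp"]   # acid stabilised in charged form
        assert lys_pka > MODEL_PKA["Lys"]
        assert res.dg_charge < 0

    def test_cap_enforced(self, solvent):
        rng = np.random.default_rng(1)
        sites = random_site_system(rng, n_sites=21, box=40.0)
        with pytest.raises(TooManySitesError):
            enumerate_titration(sites, solvent)

    def test_titration_curves_monotone_for_isolated_site(self, solvent):
        res = enumerate_titration([make_site("His", (0, 0, 0))], solvent)
        curve = res.mean_protonation[0]
        assert np.all(np.diff(curve) <= 1e-12)
        assert res.pkas[0] == pytest.approx(MODEL_PKA["His"], abs=0.05)


class TestMonteCarlo:
    def test_same_seed_identical_output(self, solvent, salt_bridge_sites):
        kw = dict(ph_grid=np.array([7.0]), n_sweeps=300, n_equil=60, seed=42)
        a = mc_titration(salt_bridge_sites, solvent, **kw)
        b = mc_titration(salt_bridge_sites, solvent, **kw)
        np.testing.assert_array_equal(a.mean_protonation, b.mean_protonation)
        assert a.dg_charge == b.dg_charge

    def test_noninteracting_recovers_model_pkas(self, solvent):
        sites = [make_site("Asp", (0, 0, 0)), make_site("Lys", (500, 0, 0))]
        res = mc_titration(sites, solvent, ph_grid=np.arange(2.0, 13.0, 0.25),
                           n_sweeps=800, n_equil=160, seed=3)
        for k, site in enumerate(sites):
            assert res.pkas[k] == pytest.approx(site.model_pKa, abs=0.15)

    @pytest.mark.parametrize("seed", [11, 12, 13, 14, 15])
    def test_agrees_with_exact_enumeration(self, solvent, seed):
        """Spot-check MC against the exact partition function (the full
        ensemble check with multiplicity-aware tolerances is in the
        acceptance suite)."""
        rng = np.random.default_rng(seed)
        sites = random_site_system(rng)
        exact = enumerate_titration(sites, solvent, ph_grid=np.array([7.0]))
        mc = mc_titration(sites, solvent, ph_grid=np.array([7.0]),
                          n_sweeps=8000, n_equil=1000, seed=seed)
        assert abs(mc.dg_charge - exact.dg_charge) <= 3 * max(mc.dg_se, 1e-3)
        z = np.abs(mc.mean_protonation[:, 0]
                   - exact.mean_protonation[:, 0]) / mc.protonation_se[:, 0]
        assert np.max(z) < 6.0
        assert np.mean(z > 3.0) <= 0.1

    def test_invalid_sweep_budget_rejected(self, solvent, salt_bridge_sites):
        with pytest.raises(ValueError):
            mc_titration(salt_bridge_sites, solvent, n_sweeps=10, n_equil=10)


class TestChargeSymmetry:
    def test_charge_inversion_leaves_energies_unchanged(self, solvent):
        """Acid/base swap with mirrored pKas preserves |W| and dG."""
        ph = 7.0
        asp = IonizableSite("a", "Asp", 4.0, np.zeros(3))
        lys = IonizableSite("b", "Lys", 10.0, np.array([4.0, 0, 0]))
        # mirrored system: base where acid was, with pKa mirrored about pH 7
        lys2 = IonizableSite("a2", "Lys", 10.0, np.zeros(3))
        asp2 = IonizableSite("b2", "Asp", 4.0, np.array([4.0, 0, 0]))
        g1 = enumerate_titration([asp, lys], solvent,
                                 ph_grid=np.array([ph])).dg_charge
        g2 = enumerate_titration([lys2, asp2], solvent,
                                 ph_grid=np.array([ph])).dg_charge
        assert g1 == pytest.approx(g2, rel=1e-9)


class TestSiteExtraction:
    def test_polyalanine_yields_termini_only(self, tmp_path):
        path = tmp_path / "polyala.pdb"
        generate_toy_structure([("Ala", (i * 4.0, 0, 0)) for i in range(5)], path)
        sites = extract_ionizable_sites(parse_structure(path))
        assert sorted(s.site_type for s in sites) == ["Cterm", "Nterm"]

    def test_asp_lys_peptide_four_sites(self, tmp_path):
        path = tmp_path / "dk.pdb"
        generate_toy_structure([("Asp", (0, 0, 0)), ("Lys", (4.0, 0, 0))], path)
        sites = extract_ionizable_sites(parse_structure(path))
        assert sorted(s.site_type for s in sites) == ["Asp", "Cterm", "Lys", "Nterm"]
        by_type = {s.site_type: s for s in sites}
        r = np.linalg.norm(by_type["Asp"].position - by_type["Lys"].position)
        assert r == pytest.approx(4.0, abs=0.01)

    def test_missing_sidechain_falls_back_to_centroid(self, tmp_path):
        path = tmp_path / "broken.pdb"
        generate_toy_structure([("Asp", (0, 0, 0)), ("Lys", (6.0, 0, 0))], path)
        txt = "\n".join(l for l in path.read_text().splitlines()
                        if " OD1" not in l and " OD2" not in l)
        path.write_text(txt + "\n")
        sites = extract_ionizable_sites(parse_structure(path))
        assert "Asp" in {s.site_type for s in sites}

    def test_disulfide_pair_excluded(self, tmp_path):
        path = tmp_path / "ss.pdb"
        generate_toy_structure([("Cys", (0, 0, 0)), ("Cys", (2.0, 0, 0)),
                                ("Cys", (20.0, 0, 0))], path)
        sites = extract_ionizable_sites(parse_structure(path))
        assert sum(s.site_type == "Cys" for s in sites) == 1


class TestFoldingAndDimerEnergies:
    def test_empty_site_list_is_zero(self, solvent):
        assert enumerate_titration([], solvent).dg_charge == 0.0
        assert mc_titration([], solvent).dg_charge == 0.0

    def test_toy_salt_bridge_stabilises(self, tmp_path, solvent):
        path = tmp_path / "sb.pdb"
        generate_toy_structure([("Asp", (0, 0, 0)), ("Lys", (4.0, 0, 0))], path)
        assert charge_folding_energy(parse_structure(path), solvent) < 0

    def test_distant_subunits_additive(self, tmp_path, solvent):
        a_sites = [("Asp", (0, 0, 0)), ("Lys", (4.0, 0, 0))]
        b_sites = [("Glu", (100.0, 0, 0)), ("Arg", (104.0, 0, 0))]
        a, b, ab = toy_dimer_pdbs(a_sites, b_sites)
        for name, txt in (("a", a), ("b", b), ("ab", ab)):
            (tmp_path / f"{name}.pdb").write_text(txt)
        ddg = dimer_charge_energy(parse_structure(tmp_path / "a.pdb"),
                                  parse_structure(tmp_path / "b.pdb"),
                                  parse_structure(tmp_path / "ab.pdb"), solvent)
        assert ddg == pytest.approx(0.0, abs=0.05)

    def test_complementary_interface_attractive(self, tmp_path, solvent):
        a_sites = [("Asp", (0, 0, 0)), ("Glu", (0, 6.0, 0))]
        b_sites = [("Lys", (4.0, 0, 0)), ("Arg", (4.0, 6.0, 0))]
        a, b, ab = toy_dimer_pdbs(a_sites, b_sites)
        for name, txt in (("a", a), ("b", b), ("ab", ab)):
            (tmp_path / f"{name}.pdb").write_text(txt)
        ddg = dimer_charge_energy(parse_structure(tmp_path / "a.pdb"),
                                  parse_structure(tmp_path / "b.pdb"),
                                  parse_structure(tmp_path / "ab.pdb"), solvent)
        assert ddg < -0.5

    def test_atom_mismatch_rejected(self, tmp_path, solvent):
        a, b, ab = toy_dimer_pdbs([("Asp", (0, 0, 0))], [("Lys", (5.0, 0, 0))])
        for name, txt in (("a", a), ("b", b)):
            (tmp_path / f"{name}.pdb").write_text(txt)
        (tmp_path / "ab.pdb").write_text(a)  # wrong merge
        with pytest.raises(ValueError, match="atom count"):
            dimer_charge_energy(parse_structure(tmp_path / "a.pdb"),
                                parse_structure(tmp_path / "b.pdb"),
                                parse_structure(tmp_path / "ab.pdb"), solvent)
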
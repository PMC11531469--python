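"""Coarse-grained topology building: bead counts, local terms, contacts,
charges, disordered-region conformations."""

import numpy as np
import pytest

import forkcg
from forkcg.io import read_pdb
from forkcg.model import (ChainSpec, ChargeContext, assign_charges,
                          coarse_grain_protein, derive_native_contacts,
                          model_idr_conformation)


class TestCoarseGrainProtein:
    def test_helix_counts(self, helix_pdb_path):
        struct = read_pdb(helix_pdb_path)
        cg = coarse_grain_protein(struct, ["A"])
        assert cg.topology.n_beads == 10
        assert len(cg.topology.bonds) == 9
        assert len(cg.topology.angles) == 8
        assert len(cg.topology.dihedrals) == 7

    def test_bead_positions_are_calpha(self, mini_pdb):
        cg = coarse_grain_protein(read_pdb(mini_pdb), ["A"])
        assert cg.topology.n_beads == 3
        np.testing.assert_allclose(cg.coords[0], [0.0, 0.0, 0.0], atol=1e-6)
        np.testing.assert_allclose(cg.coords[1], [3.55, -1.35, 0.1], atol=1e-6)

    def test_idr_span_gets_no_native_local_terms(self, helix_pdb_path):
        cg = coarse_grain_protein(read_pdb(helix_pdb_path), ["A"],
                                  idr_ranges={"A": [(1, 5)]})
        from forkcg.model import K_ANGLE_IDR, THETA0_IDR
        for i, j, k, t0, kk in cg.topology.angles:
            resids = {cg.topology.beads[x].resid for x in (i, j, k)}
            if resids & set(range(1, 6)):
                assert kk == K_ANGLE_IDR and t0 == THETA0_IDR
        for quad in cg.topology.dihedrals:
            resids = {cg.topology.beads[x].resid for x in quad[:4]}
            assert not (resids & set(range(1, 6)))

    def test_fully_resolved_chain_all_native(self, helix_pdb_path):
        cg = coarse_grain_protein(read_pdb(helix_pdb_path), ["A"])
        from forkcg.model import K_ANGLE
        assert all(a[4] == K_ANGLE for a in cg.topology.angles)

    def test_missing_chain_errors(self, mini_pdb):
        with pytest.raises(KeyError):
            coarse_grain_protein(read_pdb(mini_pdb), ["Z"])

    def test_group_tags_from_chain_spec(self, helix_pdb_path):
        spec = ChainSpec("A", tags={"donor"}, tag_ranges=[(1, 3, "tip")])
        cg = coarse_grain_protein(read_pdb(helix_pdb_path), [spec])
        assert len(cg.topology.select("tip")) == 3
        assert len(cg.topology.select("donor")) == 10


class TestBformDuplex:
    def test_geometry_matches_fiber_parameters(self, duplex):
        """Consecutive base beads rise ≈3.38 Å with ≈36°/bp twist."""
        top, coords = duplex.topology, duplex.coords
        bases = [b.index for b in top.beads
                 if b.site_kind == "base" and b.chain_id == "D1"]
        xyz = coords[bases]
        rises = np.diff(xyz[:, 2])
        np.testing.assert_allclose(rises, 3.38, atol=1e-9)
        ang = np.degrees(np.arctan2(xyz[:, 1], xyz[:, 0]))
        twists = np.diff(ang) % 360.0
        np.testing.assert_allclose(twists, 36.0, atol=1e-9)

    def test_bead_counts_with_5prime_convention(self):
        d = forkcg.generate_bform_duplex("AT")
        # per strand: 2 base + 2 sugar + 1 phosphate
        assert d.topology.n_beads == 10
        kinds = [b.site_kind for b in d.topology.beads]
        assert kinds.count("phosphate") == 2

    def test_invalid_sequence_rejected(self):
        with pytest.raises(ValueError):
            forkcg.generate_bform_duplex("ACGX")

    def test_complementary_strand(self):
        d = forkcg.generate_bform_duplex("AAAC")
        s2 = [b.name for b in d.topology.beads
              if b.chain_id == "D2" and b.site_kind == "base"]
        assert "".join(s2) == "GTTT"


class TestAssembleFork:
    @pytest.mark.parametrize("lag_gap, n_expected", [(56, 167), (16, 47)])
    def test_rpa_geometry_gap_lengths(self, lag_gap, n_expected):
        f = forkcg.assemble_fork(23, 90, 96, 33, lag_gap, seed=4)
        assert len(f.topology.select("lagging_ssDNA")) == n_expected
        assert len(f.topology.select("parental_duplex")) == 2 * (3 * 23 - 1)
        assert len(f.topology.select("leading_duplex")) == 2 * (3 * 90 - 1)
        assert len(f.topology.select("lagging_duplex")) == 2 * (3 * 96 - 1)

    def test_zero_gaps_duplex_y_fork(self):
        f = forkcg.assemble_fork(8, 8, 8, 0, 0, seed=1)
        assert "junction_bead" in f.topology.metadata
        assert len(f.topology.select("leading_ssDNA")) == 0

    def test_seed_reproducible(self):
        a = forkcg.assemble_fork(8, 10, 10, 4, 6, seed=9)
        b = forkcg.assemble_fork(8, 10, 10, 4, 6, seed=9)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_dna_bead_count_invariant(self):
        """DNA beads = 3×nt − number of strands (5′ phosphates omitted)."""
        f = forkcg.assemble_fork(8, 10, 10, 4, 6, seed=9)
        n_nt = sum(1 for b in f.topology.beads if b.site_kind == "sugar")
        n_strands = len(f.topology.chains)
        assert f.topology.n_beads == 3 * n_nt - n_strands


class TestNativeContacts:
    def _two_bead_top(self):
        from forkcg.model import ChainRecord, Topology

        top = Topology()
        top.add_bead("A", "residue", "A", 0, 2.5, 1)
        top.add_bead("B", "residue", "A", 0, 2.5, 1)
        top.chains = [ChainRecord("A", "protein", 0, 1),
                      ChainRecord("B", "protein", 1, 2)]
        return top

    @pytest.mark.parametrize("atom_sep, expected", [(6.4, 1), (6.6, 0)])
    def test_cutoff_boundary(self, atom_sep, expected):
        top = self._two_bead_top()
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        heavy = [np.array([[0.0, 0, 0]]), np.array([[atom_sep, 0, 0]])]
        cs = derive_native_contacts(top, coords, heavy, cutoff=6.5)
        assert len(cs) == expected
        if expected:
            assert cs.pairs[0][2] == pytest.approx(10.0)  # bead-bead r0

    def test_rigid_motion_invariance(self, small_toy):
        from scipy.spatial.transform import Rotation

        top, coords = small_toy.topology, small_toy.coords
        idx = top.select("cargo")
        a = derive_native_contacts(top, coords, cutoff=6.5, groups=(idx, idx))
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        b = derive_native_contacts(top, coords @ R.T + 13.0, cutoff=6.5,
                                   groups=(idx, idx))
        assert [p[:2] for p in a.pairs] == [p[:2] for p in b.pairs]
        np.testing.assert_allclose([p[2] for p in a.pairs],
                                   [p[2] for p in b.pairs], atol=1e-9)

    def test_cross_chain_set_from_structure(self, helix_pdb_path):
        # two copies of the helix as separate chains, 5 Å apart
        text = helix_pdb_path.read_text().replace("END\n", "")
        shifted = []
        for line in text.splitlines():
            x = float(line[30:38]) + 7.0
            shifted.append(line[:21] + "B" + line[22:30] + f"{x:8.3f}"
                           + line[38:])
        two = helix_pdb_path.parent / "two.pdb"
        two.write_text(text + "\n".join(shifted) + "\nEND\n")
        cg = coarse_grain_protein(read_pdb(two), ["A", "B"])
        ga = cg.topology.select()  # none tagged; use chains
        a = np.arange(0, 10)
        b = np.arange(10, 20)
        cs = derive_native_contacts(cg.topology, cg.coords, cg.heavy_atoms,
                                    cutoff=6.5, groups=(a, b))
        assert len(cs) > 0


class TestCharges:
    def test_residue_rule(self):
        from forkcg.model import ChainRecord, Topology

        top = Topology()
        for i, name in enumerate(["K", "A", "E"]):
            top.add_bead("A", "residue", name, 0, 2.5, i + 1)
        top.chains = [ChainRecord("A", "protein", 0, 3)]
        t = assign_charges(top)
        np.testing.assert_array_equal(t.q_cross, [1.0, 0.0, -1.0])
        assert t.total_protein_charge() == 0.0

    def test_phosphate_dual_context(self, duplex):
        t = assign_charges(duplex.topology)
        p = [b.index for b in duplex.topology.beads
             if b.site_kind == "phosphate"][0]
        assert t.q_intra[p] == -0.6
        assert t.q_cross[p] == -1.0
        # context selection: DNA-DNA partner uses −0.6², protein uses −1.0
        assert t.pair_charge_product(p, p) == pytest.approx(0.36)

    def test_neutralize_tags_zeroes_exactly_tagged(self, small_toy):
        t = assign_charges(small_toy.topology,
                           neutralize_tags={"carrier_loop"})
        loop = small_toy.topology.select("carrier_loop")
        assert np.all(t.q_cross[loop] == 0.0)
        t0 = assign_charges(small_toy.topology)
        others = np.setdiff1d(np.arange(small_toy.topology.n_beads), loop)
        np.testing.assert_array_equal(t.q_cross[others], t0.q_cross[others])

    def test_charge_bookkeeping_matches_composition(self, small_toy):
        top = small_toy.topology
        t = assign_charges(top)
        expect = sum(1 for b in top.beads if b.site_kind == "residue"
                     and b.name in ("K", "R", "LYS", "ARG"))
        expect -= sum(1 for b in top.beads if b.site_kind == "residue"
                      and b.name in ("D", "E", "ASP", "GLU"))
        assert t.total_protein_charge() == pytest.approx(expect)

    def test_override_out_of_range(self, duplex):
        ctx = ChargeContext(overrides=[(10**6, 1.0)])
        with pytest.raises(IndexError):
            assign_charges(duplex.topology, ctx)


class TestIDRConformation:
    def _chain_top(self, n):
        from forkcg.model import ChainRecord, Topology

        top = Topology()
        for i in range(n):
            top.add_bead("A", "residue", "A", 0, 2.5, i + 1)
        top.chains = [ChainRecord("A", "protein", 0, n)]
        return top

    def test_internal_gap_bridged_with_fixed_steps(self):
        top = self._chain_top(8)
        coords = np.full((8, 3), np.nan)
        coords[0] = [0, 0, 0]
        coords[1] = [3.8, 0, 0]
        coords[7] = [15.8, 0, 0]  # 5-residue gap across 12 Å
        out = model_idr_conformation(top, coords, seed=3)
        assert np.isfinite(out).all()
        steps = np.linalg.norm(np.diff(out[1:8], axis=0), axis=1)
        np.testing.assert_allclose(steps[:-1], 3.8, atol=0.01)

    def test_same_seed_identical(self):
        top = self._chain_top(8)
        coords = np.full((8, 3), np.nan)
        coords[0] = [0, 0, 0]
        coords[7] = [10.0, 0, 0]
        a = model_idr_conformation(top, coords, seed=5)
        b = model_idr_conformation(top, coords, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_unbridgeable_gap_errors(self):
        top = self._chain_top(7)
        coords = np.full((7, 3), np.nan)
        coords[0] = [0, 0, 0]
        coords[6] = [40.0, 0, 0]  # 6 steps × 3.8 Å < 40 Å
        with pytest.raises(ValueError, match="bridge"):
            model_idr_conformation(top, coords, seed=1)
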
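"""Bilayer assembly, solvation and counterion placement."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import cgbilayer as cg
from cgbilayer.builder import (
    SYSTEM_REGISTRY,
    BuildError,
    Composition,
    build_bilayer,
    solvate,
)

SMALL = Composition(leaflet_counts={"POPC": 8}, n_water_beads=260)
SMALL_BOX = (33.0, 33.0, 90.0)


class TestComposition:
    def test_study_composition_counts(self):
        comp = Composition(leaflet_counts={"POPC": 52, "ISUCA-Pal-Ol+": 6})
        assert comp.total_lipids == 116
        assert comp.lipids_per_leaflet == 58

    def test_waters_per_lipid(self):
        comp = Composition(leaflet_counts={"POPC": 58}, n_water_beads=1840)
        assert comp.waters_per_lipid == pytest.approx(1840 * 4 / 116)

    def test_invalid_fields_rejected(self):
        with pytest.raises(BuildError):
            Composition(leaflet_counts={"POPC": -1})
        with pytest.raises(BuildError):
            Composition(leaflet_counts={"POPC": 8}, antifreeze_fraction=1.5)


class TestBuildBilayer:
    def test_registry_90_10_protonated_counts(self, ff):
        counts, _ = SYSTEM_REGISTRY["90:10 POPC/ISUCA+-Pal-Ol"]
        assert counts == {"POPC": 52, "ISUCA-Pal-Ol+": 6}

    def test_leaflets_mirror_symmetric(self, ff):
        s = build_bilayer(SMALL, SMALL_BOX, seed=3)
        upper = [s.species[m] for m in range(s.n_molecules) if s.leaflet[m] > 0]
        lower = [s.species[m] for m in range(s.n_molecules) if s.leaflet[m] < 0]
        assert sorted(upper) == sorted(lower)
        assert len(upper) == 8

    def test_heads_outward_tails_inward(self, ff):
        s = build_bilayer(SMALL, SMALL_BOX, seed=3)
        z_mid = s.box[2] / 2
        heads = s.coords[s.lipid_bead_indices("head"), 2]
        c1 = s.coords[s.lipid_bead_indices("c1"), 2]
        assert np.all(np.abs(heads - z_mid) > np.abs(c1 - z_mid).min())

    def test_initial_apl_by_construction(self, ff):
        # the lateral box fixes the APL regardless of lipid placement
        comp = Composition(leaflet_counts={"POPC": 58})
        s = build_bilayer(comp, (62.4, 62.4, 90.0), seed=0)
        apl = s.box[0] * s.box[1] / 58
        assert apl == pytest.approx(67.1, abs=0.05)

    def test_determinism(self, ff):
        a = build_bilayer(SMALL, SMALL_BOX, seed=9)
        b = build_bilayer(SMALL, SMALL_BOX, seed=9)
        assert np.array_equal(a.coords, b.coords)
        assert a.species == b.species

    def test_no_overlaps(self, ff):
        s = build_bilayer(SMALL, SMALL_BOX, seed=4)
        tree = cKDTree(np.mod(s.coords, s.box), boxsize=s.box)
        pairs = tree.query_pairs(1.8, output_type="ndarray")
        inter = [
            p for p in pairs if s.mol_index[p[0]] != s.mol_index[p[1]]
        ]
        assert not inter

    def test_box_too_small_rejected(self, ff):
        with pytest.raises(BuildError, match="box too small"):
            build_bilayer(SMALL, (15.0, 15.0, 90.0), seed=0)


class TestSolvate:
    def test_antifreeze_split_30pct(self, ff):
        s = build_bilayer(SMALL, SMALL_BOX, seed=1)
        s = solvate(s, 260, 0.30, seed=2)
        n_wf = s.species.count("WF")
        n_w = s.species.count("W")
        assert n_wf == round(0.30 * 260)
        assert n_w + n_wf == 260

    def test_zero_antifreeze(self, ff):
        s = build_bilayer(SMALL, SMALL_BOX, seed=1)
        s = solvate(s, 100, 0.0, seed=2)
        assert s.species.count("WF") == 0
        assert s.species.count("W") == 100

    def test_study_system_bead_bookkeeping(self, ff):
        # lipids x beads-per-lipid + solvent (+ ions) = total, per Table-4-like
        s = cg.build_named_system("POPC", seed=0)
        assert s.n_beads == 116 * 12 + 1840
        s = cg.build_named_system("90:10 POPC/ISUCA+-Pal-Ol", seed=0)
        assert s.n_beads == 104 * 12 + 12 * 13 + 1840
        assert s.species.count("CL") == 12
        assert s.net_charge == 0

    def test_insufficient_volume_rejected(self, ff):
        s = build_bilayer(SMALL, SMALL_BOX, seed=1)
        with pytest.raises(BuildError, match="insufficient volume"):
            solvate(s, 50000, 0.3, seed=2)


class TestCounterions:
    def test_protonated_system_neutralized(self, ff):
        comp = Composition(
            leaflet_counts={"POPC": 6, "ISUCA-Pal-Ol+": 2}, n_water_beads=260
        )
        s = build_bilayer(comp, SMALL_BOX, seed=5)
        s = solvate(s, 260, 0.3, seed=6)
        assert s.net_charge == 4
        n_before = s.n_beads
        s = cg.add_counterions(s, seed=7)
        assert s.net_charge == 0
        assert s.n_beads == n_before  # ions replace water beads
        assert s.species.count("CL") == 4
        assert s.species.count("W") == 260 - round(0.3 * 260) - 4

    def test_neutral_system_noop_with_warning(self, ff):
        s = build_bilayer(SMALL, SMALL_BOX, seed=5)
        with pytest.warns(UserWarning, match="neutral"):
            out = cg.add_counterions(s, seed=1)
        assert out.n_beads == s.n_beads
        assert out.species == s.species
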
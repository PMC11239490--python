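"""Fragment enumeration, Domon-Costello naming, matching and prioritization."""

import itertools

import numpy as np
import pytest

from glycrunch.fragments import (
    Cleavage,
    annotate_spectrum,
    enumerate_connected_subgraphs,
    enumerate_fragments,
    fragment_neutral_mass,
    match_peaks,
    parse_dc_name,
    prioritize,
)
from glycrunch.glycans import parse_iupac
from glycrunch.masses import IonSpec, PROTON, glycan_mass, ion_mz

from conftest import random_tree

Z1_NEG = [IonSpec("negative", None, 1)]


def brute_force_subgraphs(g):
    """Oracle: all non-empty node subsets that induce a connected subtree."""
    out = set()
    for r in range(1, g.n_nodes + 1):
        for combo in itertools.combinations(range(g.n_nodes), r):
            keep = set(combo)
            roots = [i for i in keep if g.parents[i] not in keep]
            if len(roots) != 1:
                continue
            # connected iff every node reaches the unique local root inside keep
            ok = True
            for i in keep:
                j = i
                while j != roots[0]:
                    j = g.parents[j]
                    if j not in keep:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                out.add(frozenset(keep))
    return out


class TestSubgraphEnumeration:
    def test_three_node_branch_has_six(self, branch_trisaccharide):
        assert len(enumerate_connected_subgraphs(branch_trisaccharide)) == 6

    def test_singleton(self):
        assert enumerate_connected_subgraphs(parse_iupac("Gal")) == [frozenset({0})]

    def test_linear_chain_has_six(self, linear_trisaccharide):
        subs = enumerate_connected_subgraphs(linear_trisaccharide)
        assert len(subs) == 6 and len(set(subs)) == 6

    def test_matches_brute_force_on_random_trees(self, rng):
        for _ in range(50):
            g = random_tree(rng, int(rng.integers(1, 9)))
            ours = set(enumerate_connected_subgraphs(g))
            assert ours == brute_force_subgraphs(g)


class TestEnumerateFragments:
    def test_disaccharide_glycosidic_ion_set(self, core1_reduced):
        frs = enumerate_fragments(core1_reduced, ions=Z1_NEG, allow_cross_ring=False)
        names = {f.dc_name for f in frs if not f.global_mods}
        assert names == {"B1", "C1", "Y1", "Z1", "M"}

    def test_max_cleavages_one_excludes_internal_fragments(self, linear_trisaccharide):
        frs = enumerate_fragments(
            linear_trisaccharide, ions=Z1_NEG, max_cleavages=1, allow_cross_ring=False
        )
        assert all(len(f.cleavages) <= 1 for f in frs)
        # the middle residue alone would need two cleavages
        assert frozenset({1}) not in {f.nodes for f in frs} or all(
            f.nodes != frozenset({linear_trisaccharide.children(linear_trisaccharide.root)[0]})
            for f in frs
        )

    def test_single_cleavage_subgraph_count_is_two_per_edge(self, branch_trisaccharide):
        frs = enumerate_fragments(
            branch_trisaccharide, ions=Z1_NEG, max_cleavages=1, allow_cross_ring=False
        )
        n_edges = branch_trisaccharide.n_nodes - 1
        single = {f.nodes for f in frs if len(f.cleavages) == 1}
        intact = {f.nodes for f in frs if not f.cleavages}
        assert len(single) == 2 * n_edges
        assert len(intact) == 1

    def test_b_and_y_masses(self, core1_reduced):
        frs = {
            f.dc_name: f
            for f in enumerate_fragments(core1_reduced, ions=Z1_NEG, allow_cross_ring=False)
            if not f.global_mods
        }
        # B1 = dehydrated Gal residue as anhydro-oxocarbenium precursor
        assert frs["B1"].neutral_mass == pytest.approx(162.0528, abs=5e-4)
        # Y1 = reduced GalNAc + water
        assert frs["Y1"].neutral_mass == pytest.approx(223.1056, abs=5e-4)

    def test_theo_mz_recomputable(self, branch_trisaccharide):
        for f in enumerate_fragments(branch_trisaccharide, ions=Z1_NEG):
            neutral = fragment_neutral_mass(
                f.parent, f.nodes, f.cleavages, f.ring_cuts, f.global_mods
            )
            assert ion_mz(neutral, f.ion) == pytest.approx(f.theo_mz, abs=1e-6)

    def test_cross_ring_fragments_respect_attachment_positions(self):
        # Neu5Ac sits on position 6: a 0,2A cut of the root keeps positions 3,4,6
        g = parse_iupac("GlcNAcβ1-3(Neu5Acα2-6)GalNAc")
        frs = enumerate_fragments(g, ions=Z1_NEG, allow_cross_ring=True)
        a_roots = {f.dc_name for f in frs if any(s == "A" for _, _, s in f.ring_cuts)}
        assert any(name.startswith("0,2A") for name in a_roots)


class TestDomonCostelloNames:
    def test_b3_counts_from_nonreducing_terminus(self):
        tet = parse_iupac("Neu5Acα2-3Galβ1-4GlcNAcβ1-2Man", reduced=True)
        frs = enumerate_fragments(tet, ions=Z1_NEG, allow_cross_ring=False, max_cleavages=1)
        b3 = [f for f in frs if f.dc_name == "B3" and not f.global_mods]
        assert len(b3) == 1 and len(b3[0].nodes) == 3

    def test_terminal_sialic_acid_is_b1(self, linear_trisaccharide):
        frs = enumerate_fragments(
            linear_trisaccharide, ions=Z1_NEG, allow_cross_ring=False
        )
        b1 = [f for f in frs if f.dc_name == "B1" and not f.global_mods]
        assert len(b1) == 1
        (node,) = b1[0].nodes
        assert linear_trisaccharide.labels[node] == "Neu5Ac"

    def test_intact_species_is_named_m(self, core1_reduced):
        frs = enumerate_fragments(core1_reduced, ions=Z1_NEG)
        m = [f for f in frs if not f.cleavages and not f.global_mods]
        assert len(m) == 1 and m[0].dc_name == "M"
        assert m[0].theo_mz == pytest.approx(
            glycan_mass(core1_reduced) - PROTON, abs=1e-6
        )

    def test_wrong_parent_rejected(self, core1_reduced, branch_trisaccharide):
        from glycrunch.fragments import domon_costello_name

        f = enumerate_fragments(core1_reduced, ions=Z1_NEG)[0]
        with pytest.raises(ValueError):
            domon_costello_name(f, branch_trisaccharide)

    @pytest.mark.parametrize(
        "glycan",
        [
            "Galβ1-3GalNAc",
            "Neu5Acα2-3Galβ1-3(GlcNAcβ1-6)GalNAc",
            "Fucα1-2Galβ1-4GlcNAcβ1-3Galβ1-4Glc",
        ],
    )
    def test_name_roundtrip_over_all_fragments(self, glycan):
        g = parse_iupac(glycan, reduced=True)
        for f in enumerate_fragments(g, ions=Z1_NEG):
            parsed = parse_dc_name(f.dc_name)
            expected = sorted(
                f.cleavages, key=lambda c: ({"B": 0, "C": 1, "A": 2, "Y": 3, "Z": 4, "X": 5}[c.kind], c.index, c.branch)
            )
            assert parsed == expected

    def test_cleavage_validation(self):
        with pytest.raises(ValueError):
            Cleavage("A", 1)  # cross-ring without ring bonds
        with pytest.raises(ValueError):
            Cleavage("B", 1, ring_bonds=(0, 2))


class TestComplementarity:
    def test_by_pairs_partition_nodes_and_conserve_mass(self, rng):
        for glycan in (
            "Neu5Acα2-3Galβ1-3GalNAc",
            "Neu5Acα2-3Galβ1-3(GlcNAcβ1-6)GalNAc",
            "Fucα1-2Galβ1-4GlcNAcβ1-3Galβ1-4Glc",
        ):
            g = parse_iupac(glycan, reduced=True)
            frs = [
                f
                for f in enumerate_fragments(g, ions=Z1_NEG, max_cleavages=1, allow_cross_ring=False)
                if not f.global_mods
            ]
            all_nodes = frozenset(range(g.n_nodes))
            bs = [f for f in frs if f.dc_name.startswith("B")]
            ys = {f.nodes: f for f in frs if f.dc_name.startswith("Y")}
            assert bs
            for b in bs:
                comp = all_nodes - b.nodes
                assert comp in ys  # complementary Y exists
                total = b.neutral_mass + ys[comp].neutral_mass
                assert total == pytest.approx(glycan_mass(g), abs=1e-6)


class TestMatchingAndPrioritization:
    def test_exact_peak_is_rank_one_with_zero_error(self, core1_reduced):
        frs = enumerate_fragments(core1_reduced, ions=Z1_NEG, allow_cross_ring=False)
        target = next(f for f in frs if f.dc_name == "B1" and not f.global_mods)
        anns = match_peaks(frs, [(target.theo_mz, 1.0)], tolerance=0.5)
        assert anns[0].candidates[0].theo_mz == pytest.approx(target.theo_mz, abs=1e-9)
        assert anns[0].mass_errors[0] == pytest.approx(0.0, abs=1e-9)

    def test_far_peak_gets_no_candidates(self, core1_reduced):
        frs = enumerate_fragments(core1_reduced, ions=Z1_NEG)
        anns = match_peaks(frs, [(5000.0, 1.0)], tolerance=0.5)
        assert anns[0].candidates == []

    def test_single_candidate_is_unchanged(self, core1_reduced):
        frs = enumerate_fragments(core1_reduced, ions=Z1_NEG)
        assert prioritize([frs[0]]) == [frs[0]]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            prioritize([])

    def test_fewer_cleavages_outrank_internal_fragments(self):
        g = parse_iupac("Neu5Acα2-3Galβ1-4GlcNAcβ1-2Man", reduced=True)
        frs = enumerate_fragments(g, ions=Z1_NEG, allow_cross_ring=False)
        b2 = next(f for f in frs if f.dc_name == "B2" and not f.global_mods)
        internal = next(
            f for f in frs if len(f.cleavages) == 2 and not f.global_mods
        )
        ranked = prioritize([internal, b2])
        assert ranked[0] is b2

    def test_corroborated_candidate_ranks_first(self, linear_trisaccharide):
        g = parse_iupac(str(linear_trisaccharide.canonical), reduced=True)
        frs = enumerate_fragments(g, ions=Z1_NEG, allow_cross_ring=False)
        b1 = next(f for f in frs if f.dc_name == "B1" and not f.global_mods)
        y2 = next(f for f in frs if f.dc_name == "Y2" and not f.global_mods)
        z1 = next(f for f in frs if f.dc_name == "Z1" and not f.global_mods)
        # context contains Y2, the complement of B1 — corroborates B1 over Z1
        context = match_peaks(frs, [(y2.theo_mz, 1.0)], tolerance=0.01)
        ranked = prioritize([z1, b1], spectrum_context=context)
        assert ranked[0].dc_name == "B1"


class TestSelfConsistency:
    def test_noiseless_annotation_recovers_generators(self, rng):
        from glycrunch.simulate import SimParams, simulate_spectrum

        g = parse_iupac("Neu5Acα2-3Galβ1-3(GlcNAcβ1-6)GalNAc", reduced=True)
        params = SimParams(n_noise_peaks=0, mz_jitter_sd=0.0, fragment_keep_prob=1.0)
        spectrum, provenance = simulate_spectrum(g, params, rng, return_provenance=True)
        anns = annotate_spectrum(
            g, spectrum.peaks.tolist(), tolerance=0.01, ions=Z1_NEG, allow_cross_ring=False
        )
        for ann, gens in zip(anns, provenance):
            assert gens is not None
            best = ann.best
            assert best is not None
            gen_nodes = {f.nodes for f in gens}
            gen_masses = {round(f.neutral_mass, 6) for f in gens}
            assert best.nodes in gen_nodes or round(best.neutral_mass, 6) in gen_masses
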
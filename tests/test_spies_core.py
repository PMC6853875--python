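"""The 3D-SPIEs screen: distances, filtering, classes, bridges, maps."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from spies3d.pieda_parse import PIETable, PairInteraction
from spies3d.spies_core import (
    SPIESParams,
    all_pair_distances,
    build_interaction_map,
    classify_pairs,
    detect_water_bridges,
    export_scatter,
    hotspot_regions,
    min_fragment_distance,
    read_spie_records,
    spies_filter,
    write_spie_records,
)
from spies3d.fragmentation import build_fragmentation

from conftest import make_record, point_cloud_plan


def brute_force_min(structure, plan, i, j):
    frag = {f.index: f for f in plan.fragments}
    coords = {
        (r.chain_id, r.resseq, r.icode, a.name): np.array(a.coords)
        for r in structure
        for a in r.atoms
    }
    return min(
        float(np.linalg.norm(coords[a] - coords[b]))
        for a in frag[i].member_atoms
        for b in frag[j].member_atoms
    )


class TestDistances:
    def test_three_four_five(self):
        rng = np.random.default_rng(0)
        plan, structure = point_cloud_plan(rng, 2, max_atoms=1)
        # overwrite to exact single points
        from spies3d.structure_model import Atom, Residue, Structure
        from spies3d.fragmentation import Fragment, FragmentationPlan

        def single(i, xyz):
            atoms = (Atom(serial=i, name="O", element="O", coords=xyz),)
            res = Residue(chain_id="W", resseq=i, icode="", resname="HOH",
                          atoms=atoms, kind="water", het=True)
            frag = Fragment(index=i, label=f"HOH{i}:W",
                            member_atoms=frozenset({("W", i, "", "O")}),
                            charge=0, kind="water", source_residues=(("W", i, ""),))
            return res, frag

        r1, f1 = single(1, (0.0, 0.0, 0.0))
        r2, f2 = single(2, (3.0, 4.0, 0.0))
        structure = Structure(residues=(r1, r2), chain_order=("W",))
        plan = FragmentationPlan(fragments=(f1, f2), detached_bonds=(), total_charge=0)
        assert min_fragment_distance(plan, structure, 1, 2) == pytest.approx(5.0)
        assert min_fragment_distance(plan, structure, 2, 1) == pytest.approx(5.0)

    def test_adjacent_peptide_fragments_touch_at_detached_bond(self, ala3):
        plan = build_fragmentation(ala3)
        d = min_fragment_distance(plan, ala3, 1, 2)
        # fragment 2 holds residue 1's carbonyl C, bonded to residue 1's Cα
        assert d < 1.8
        assert d == pytest.approx(brute_force_min(ala3, plan, 1, 2))

    @pytest.mark.parametrize("seed", range(10))
    def test_min_distance_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        plan, structure = point_cloud_plan(rng, 5)
        for i, j in itertools.combinations(range(1, 6), 2):
            assert min_fragment_distance(plan, structure, i, j) == pytest.approx(
                brute_force_min(structure, plan, i, j), abs=1e-12
            )

    def test_collinear_cutoff(self):
        from spies3d.structure_model import Atom, Residue, Structure
        from spies3d.fragmentation import Fragment, FragmentationPlan

        residues, frags = [], []
        for i, x in enumerate([0.0, 5.0, 10.0], start=1):
            atoms = (Atom(serial=i, name="O", element="O", coords=(x, 0.0, 0.0)),)
            residues.append(Residue(chain_id="W", resseq=i, icode="", resname="HOH",
                                    atoms=atoms, kind="water", het=True))
            frags.append(Fragment(index=i, label=f"W{i}",
                                  member_atoms=frozenset({("W", i, "", "O")}),
                                  charge=0, kind="water", source_residues=(("W", i, ""),)))
        structure = Structure(residues=tuple(residues), chain_order=("W",))
        plan = FragmentationPlan(fragments=tuple(frags), detached_bonds=(), total_charge=0)
        got = all_pair_distances(plan, structure, cutoff=5.4)
        assert set(got) == {(1, 2), (2, 3)}

    def test_tiny_cutoff_empty(self, toy_complex, toy_plan):
        assert all_pair_distances(toy_plan, toy_complex, cutoff=0.1) == {}

    @pytest.mark.parametrize("seed", range(8))
    def test_kdtree_backend_equals_naive(self, seed):
        rng = np.random.default_rng(100 + seed)
        plan, structure = point_cloud_plan(rng, 8)
        cutoff = float(rng.uniform(3.0, 15.0))
        kd = all_pair_distances(plan, structure, cutoff, backend="kdtree")
        naive = all_pair_distances(plan, structure, cutoff, backend="naive")
        assert set(kd) == set(naive)
        for k in kd:
            assert kd[k] == pytest.approx(naive[k], abs=1e-12)

    def test_toy_complex_pairs_match_brute_force(self, toy_complex, toy_plan):
        got = all_pair_distances(toy_plan, toy_complex, cutoff=5.4)
        n = len(toy_plan)
        expected = {}
        for i, j in itertools.combinations(range(1, n + 1), 2):
            d = brute_force_min(toy_complex, toy_plan, i, j)
            if d <= 5.4:
                expected[(i, j)] = d
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k], abs=1e-9)


def _pie(i, j, total, g_sol=0.0):
    return PairInteraction(
        frag_i=i, frag_j=j, e_es=total - g_sol, e_ex=0.0, e_ct_mix=0.0, e_di=0.0,
        g_sol=g_sol, total=total,
    )


class TestFilter:
    def test_inclusive_boundaries(self, toy_complex, toy_plan):
        distances = all_pair_distances(toy_plan, toy_complex, cutoff=100.0)
        # take any real pair and pin its distance at exactly the cutoff
        (i, j) = next(iter(distances))
        table = PIETable(records=(_pie(i, j, -3.0),), n_fragments=len(toy_plan))
        recs = spies_filter(table, {(i, j): 5.4}, toy_plan, SPIESParams())
        assert len(recs) == 1  # 5.4 Å and −3.0 kcal/mol are both retained
        assert spies_filter(table, {(i, j): 5.5}, toy_plan, SPIESParams()) == []
        weak = PIETable(records=(_pie(i, j, -2.999),), n_fragments=len(toy_plan))
        assert spies_filter(weak, {(i, j): 5.4}, toy_plan, SPIESParams()) == []

    def test_matches_brute_force_predicate(self, toy_complex, toy_plan):
        rng = np.random.default_rng(7)
        distances = all_pair_distances(toy_plan, toy_complex, cutoff=50.0)
        pairs = list(distances)[:20]
        table = PIETable(
            records=tuple(_pie(i, j, float(rng.uniform(-12, 4))) for i, j in pairs),
            n_fragments=len(toy_plan),
        )
        params = SPIESParams(distance_cutoff=5.4, attractive_threshold=-3.0)
        got = {(r.frag_i, r.frag_j) for r in spies_filter(table, distances, toy_plan, params)}
        expected = {
            (r.frag_i, r.frag_j)
            for r in table.records
            if distances[(r.frag_i, r.frag_j)] <= 5.4 and r.pie <= -3.0
        }
        assert got == expected

    @settings(
        derandomize=True,
        max_examples=60,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        d1=st.floats(1.0, 10.0),
        d2=st.floats(1.0, 10.0),
        e1=st.floats(-10.0, 2.0),
        e2=st.floats(-10.0, 2.0),
    )
    def test_monotone_in_both_cutoffs(self, toy_complex, toy_plan, d1, d2, e1, e2):
        """Relaxing either cutoff never removes a retained record."""
        distances = all_pair_distances(toy_plan, toy_complex, cutoff=100.0)
        rng = np.random.default_rng(11)
        table = PIETable(
            records=tuple(
                _pie(i, j, float(rng.uniform(-12, 4))) for i, j in list(distances)[:15]
            ),
            n_fragments=len(toy_plan),
        )
        lo_d, hi_d = sorted((d1, d2))
        lo_e, hi_e = sorted((e1, e2))
        tight = SPIESParams(distance_cutoff=lo_d, attractive_threshold=lo_e)
        loose = SPIESParams(distance_cutoff=hi_d, attractive_threshold=hi_e)
        kept_tight = {(r.frag_i, r.frag_j) for r in spies_filter(table, distances, toy_plan, tight)}
        kept_loose = {(r.frag_i, r.frag_j) for r in spies_filter(table, distances, toy_plan, loose)}
        assert kept_tight <= kept_loose

    def test_pair_missing_from_plan_dropped_with_warning(self, toy_complex, toy_plan):
        n = len(toy_plan)
        table = PIETable(records=(_pie(n + 3, n + 4, -9.0),), n_fragments=n + 4)
        with pytest.warns(UserWarning, match="not in fragmentation plan"):
            assert spies_filter(table, {(n + 3, n + 4): 1.0}, toy_plan) == []


class TestClassification:
    def test_same_group_is_intra(self):
        rec = make_record("_L_D61", "_L_R113", chain_i="B", chain_j="B",
                          resseq_i=61, resseq_j=113, pie=-14.636)
        (out,) = classify_pairs([rec], {"B": "PDL1"})
        assert out.iclass == "intra_group"

    def test_cross_group_is_inter(self):
        rec = make_record("I134", "_L_Y123", chain_i="C", chain_j="B",
                          resseq_i=134, resseq_j=123)
        (out,) = classify_pairs([rec], {"C": "PD1", "B": "PDL1"})
        assert out.iclass == "inter_group"

    def test_water_partner_is_water_mediated(self):
        rec = make_record("N66", "HOH203", chain_i="C", chain_j="W",
                          kind_j="water", resseq_i=66, resseq_j=203)
        (out,) = classify_pairs([rec], {"C": "PD1", "W": "water"})
        assert out.iclass == "water_mediated"

    def test_two_waters_are_water_water(self):
        rec = make_record("HOH202", "HOH203", chain_i="W", chain_j="W",
                          kind_i="water", kind_j="water")
        (out,) = classify_pairs([rec], {})
        assert out.iclass == "water_water"

    def test_unmapped_protein_chain_raises(self):
        rec = make_record("A1", "B1", chain_i="A", chain_j="B")
        with pytest.raises(KeyError):
            classify_pairs([rec], {"A": "G1"})

    def test_classification_is_a_partition(self, toy_complex, toy_plan):
        distances = all_pair_distances(toy_plan, toy_complex, cutoff=6.0)
        rng = np.random.default_rng(2)
        table = PIETable(
            records=tuple(_pie(i, j, float(rng.uniform(-8, -4))) for i, j in distances),
            n_fragments=len(toy_plan),
        )
        recs = classify_pairs(
            spies_filter(table, distances, toy_plan), {"A": "G1", "B": "G2"}
        )
        assert recs and all(
            r.iclass in ("inter_group", "intra_group", "water_mediated", "water_water")
            for r in recs
        )


class TestWaterBridges:
    def test_printed_bridge_recovered_from_its_legs(self):
        legs = [
            make_record("I134", "HOH202", chain_i="C", chain_j="W", kind_j="water",
                        resseq_i=134, resseq_j=202, pie=-5.0,
                        iclass="water_mediated", group_i="PD1", group_j="water"),
            make_record("HOH202", "_L_Y56", chain_i="W", chain_j="B", kind_i="water",
                        resseq_i=202, resseq_j=56, pie=-6.5,
                        iclass="water_mediated", group_i="water", group_j="PDL1"),
        ]
        (bridge,) = detect_water_bridges(legs)
        assert bridge.water_label == "HOH202"
        assert {bridge.partner_a, bridge.partner_b} == {"I134", "_L_Y56"}
        assert {bridge.pie_a, bridge.pie_b} == {-5.0, -6.5}

    def test_same_group_partners_make_no_bridge(self):
        legs = [
            make_record("I134", "HOH202", chain_i="C", chain_j="W", kind_j="water",
                        iclass="water_mediated", group_i="PD1", group_j="water"),
            make_record("HOH202", "N66", chain_i="W", chain_j="C", kind_i="water",
                        iclass="water_mediated", group_i="water", group_j="PD1"),
        ]
        assert detect_water_bridges(legs) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_triple_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        groups = ["G1", "G2"]
        records = []
        for w in range(1, 4):
            for p in range(1, 6):
                if rng.random() < 0.5:
                    continue
                g = groups[p % 2]
                records.append(
                    make_record(
                        f"R{p}", f"HOH{w}", chain_i="AB"[p % 2], chain_j="W",
                        kind_j="water", resseq_i=p, resseq_j=w,
                        pie=float(rng.uniform(-9, -3)),
                        iclass="water_mediated", group_i=g, group_j="water",
                    )
                )
        got = {
            (b.water_label, tuple(sorted((b.partner_a, b.partner_b))))
            for b in detect_water_bridges(records)
        }
        # oracle: brute-force triple loop over retained water-mediated legs
        expected = set()
        for a in records:
            for b in records:
                if a is b or a.label_j != b.label_j:
                    continue
                if a.group_i != b.group_i:
                    expected.add((a.label_j, tuple(sorted((a.label_i, b.label_i)))))
        assert got == expected


class TestHotspots:
    def _recs(self, resseqs, group="PD1", partner_group="PDL1"):
        return [
            make_record(f"X{s}", f"_L_Y{k}", chain_i="C", chain_j="B",
                        resseq_i=s, resseq_j=100 + k, iclass="inter_group",
                        group_i=group, group_j=partner_group)
            for k, s in enumerate(resseqs)
        ]

    def test_gap_within_tolerance_is_one_region(self):
        (region,) = hotspot_regions(self._recs([132, 133, 134, 136]), "PD1", gap_tolerance=2)
        assert region.span == (132, 136)
        assert region.residues == (132, 133, 134, 136)
        assert region.support == 4

    def test_large_gap_splits_regions(self):
        regions = hotspot_regions(self._recs([66, 75]), "PD1", gap_tolerance=2)
        assert [r.span for r in regions] == [(66, 66), (75, 75)]

    def test_no_inter_group_records_gives_empty(self):
        recs = [make_record("A1", "A2", iclass="intra_group", group_i="G", group_j="G")]
        assert hotspot_regions(recs, "G") == []

    def test_wildtype_ppi_listing_touches_ten_partner_residues(self):
        # the 13 wild-type PD-1:PD-L1 contacts reported for this interface
        listed = [
            ("Y68", 68, "_L_D122", 122), ("Q75", 75, "_L_D26", 26),
            ("Q75", 75, "_L_R125", 125), ("A132", 132, "_L_Q66", 66),
            ("I134", 134, "_L_Y56", 56), ("I134", 134, "_L_E58", 58),
            ("I134", 134, "_L_Y123", 123), ("E136", 136, "_L_R113", 113),
            ("E136", 136, "_L_Y123", 123), ("E136", 136, "_L_R125", 125),
            ("N66", 66, "_L_D122", 122), ("Q75", 75, "_L_I126", 126),
            ("K78", 78, "_L_T20", 20),
        ]
        recs = [
            make_record(a, b, chain_i="C", chain_j="B", resseq_i=sa, resseq_j=sb,
                        iclass="inter_group", group_i="PD1", group_j="PDL1")
            for a, sa, b, sb in listed
        ]
        regions = hotspot_regions(recs, "PDL1", gap_tolerance=2)
        assert sum(len(r.residues) for r in regions) == 10


class TestInteractionMap:
    def test_commonality_counts(self):
        c1 = [make_record("R10", "P1", resseq_i=10, iclass="inter_group",
                          group_i="T", group_j="P"),
              make_record("R20", "P2", resseq_i=20, iclass="inter_group",
                          group_i="T", group_j="P")]
        c2 = [make_record("R10", "P3", resseq_i=10, iclass="inter_group",
                          group_i="T", group_j="P")]
        imap = build_interaction_map({"c1": c1, "c2": c2}, "T")
        assert imap.residues == ("R10", "R20")
        assert imap.commonality == (2, 1)

    def test_empty_record_set_gives_all_false_column(self):
        c1 = [make_record("R10", "P1", resseq_i=10, iclass="inter_group",
                          group_i="T", group_j="P")]
        imap = build_interaction_map({"c1": c1, "empty": []}, "T")
        col = [row[list(imap.complexes).index("empty")] for row in imap.present]
        assert col == [False]

    def test_five_synthetic_antibodies_share_two_residues(self):
        # residues 56 and 58 are hit in all five complexes, others in one each
        sets = {}
        for k in range(5):
            recs = [
                make_record("_L_Y56", f"H{k}", resseq_i=56, iclass="inter_group",
                            group_i="PDL1", group_j=f"AB{k}"),
                make_record("_L_E58", f"H{k}", resseq_i=58, iclass="inter_group",
                            group_i="PDL1", group_j=f"AB{k}"),
                make_record(f"_L_X{70 + k}", f"H{k}", resseq_i=70 + k,
                            iclass="inter_group", group_i="PDL1", group_j=f"AB{k}"),
            ]
            sets[f"ab{k}"] = recs
        imap = build_interaction_map(sets, "PDL1")
        full = [r for r, c in zip(imap.residues, imap.commonality) if c == 5]
        assert sorted(full) == ["_L_E58", "_L_Y56"]

    def test_inconsistent_labels_raise(self):
        c1 = [make_record("_L_Y56", "P", resseq_i=56, iclass="inter_group",
                          group_i="T", group_j="P")]
        c2 = [make_record("Y56", "P", resseq_i=56, iclass="inter_group",
                          group_i="T", group_j="P")]
        with pytest.raises(ValueError, match="inconsistent"):
            build_interaction_map({"c1": c1, "c2": c2}, "T")

    def test_strongest_pie_is_most_negative(self):
        c1 = [
            make_record("R10", "P1", resseq_i=10, pie=-4.0, iclass="inter_group",
                        group_i="T", group_j="P"),
            make_record("R10", "P2", resseq_i=10, pie=-9.0, iclass="inter_group",
                        group_i="T", group_j="P"),
        ]
        imap = build_interaction_map({"c1": c1}, "T")
        assert imap.strongest[0][0] == pytest.approx(-9.0)


class TestScatterAndCSV:
    def test_one_record_scatter(self):
        rec = make_record("A1", "B1", distance=4.25, pie=-6.0)
        (dot,) = export_scatter([rec])
        assert dot["z"] == pytest.approx(4.25)
        assert dot["x"] == "A1" and dot["y"] == "B1"

    def test_empty_scatter_is_valid_json(self):
        assert json.loads(json.dumps(export_scatter([]))) == []

    def test_scatter_json_roundtrip(self):
        rng = np.random.default_rng(5)
        recs = [
            make_record(f"A{i}", f"B{i}", distance=float(rng.uniform(1, 5.4)),
                        pie=float(rng.uniform(-12, -3)))
            for i in range(25)
        ]
        dots = export_scatter(recs)
        back = json.loads(json.dumps(dots))
        assert back == dots

    def test_record_csv_roundtrip(self, tmp_path):
        recs = classify_pairs(
            [make_record("A1", "B1", chain_i="A", chain_j="B", distance=3.3, pie=-4.5)],
            {"A": "G1", "B": "G2"},
        )
        p = tmp_path / "spies.csv"
        write_spie_records(recs, p)
        back = read_spie_records(p)
        assert len(back) == 1
        assert back[0].iclass == "inter_group"
        assert back[0].pie == pytest.approx(-4.5)
        assert back[0].distance == pytest.approx(3.3)
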
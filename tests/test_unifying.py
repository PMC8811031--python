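"""LCA grouping, conditional co-occurrence, and the primary/complication split."""

import numpy as np
import pytest

import unidiag as u

from conftest import make_patients


class TestGroupLCoP:
    def test_printed_cluster2_pattern_gives_seven_entries(self, tdccop2, tree):
        entries = u.lcop_order(u.group_lcop(tdccop2, tree), tdccop2)
        assert {(e.node, e.order) for e in entries} == {
            ("580–629", 1),
            ("038.9", 2),
            ("460–519", 3),
            ("390–459", 5),
            ("785.52", 8),
            ("240–279", 9),
            ("995.92", 10),
        }

    def test_codes_under_one_subcategory_merge_there(self, tree):
        t = u.TDCCoP.from_summaries(["550.12", "550.13"], [2.0, 3.0])
        entries = u.group_lcop(t, tree)
        assert len(entries) == 1 and entries[0].node == "550.1"

    def test_cross_chapter_codes_stay_singletons(self, tree):
        t = u.TDCCoP.from_summaries(["038.9", "428.0", "715.90"], [1.0, 2.0, 3.0])
        entries = u.group_lcop(t, tree)
        assert {e.node for e in entries} == {"038.9", "428.0", "715.90"}

    def test_partition_property(self, tdccop2, tree):
        entries = u.group_lcop(tdccop2, tree)
        members = [m for e in entries for m in e.members]
        assert sorted(members) == sorted(tdccop2.codes)
        for e in entries:
            assert e.node != "ROOT"
            if len(e.members) == 1:
                assert e.node == e.members[0]
            else:
                for m in e.members:
                    assert tree.is_a(m, e.node)

    def test_entry_order_is_min_member_rank(self, tdccop2, tree):
        entries = u.lcop_order(u.group_lcop(tdccop2, tree), tdccop2)
        for e in entries:
            assert e.order == min(tdccop2.rank_of(m) for m in e.members)


@pytest.fixture()
def six_patient_core(tree):
    """Hand-enumerable co-occurrence fixture over three LCoP entries."""
    patients = make_patients(
        {
            "a": [("584.9", 1), ("038.9", 2)],
            "b": [("584.9", 1), ("038.9", 3), ("428.0", 2)],
            "c": [("584.9", 2), ("428.0", 1)],
            "d": [("038.9", 1)],
            "e": [("584.9", 1)],
            "f": [("599.0", 1), ("038.9", 2)],
        }
    )
    ids = [p.patient_id for p in patients]
    S = u.SimilarityMatrix(ids=ids, values=np.eye(6) * 0 + np.eye(6))
    core = u.CoreZone(
        cluster=0, exemplar_id="a", patients=patients, mode="threshold", param=0.0
    )
    entries = [
        u.LCoPEntry(node="580–629", members=("584.9", "599.0"), order=1),
        u.LCoPEntry(node="038.9", members=("038.9",), order=2),
        u.LCoPEntry(node="428.0", members=("428.0",), order=3),
    ]
    return patients, core, entries


class TestCCoM:
    def test_matches_hand_counts(self, six_patient_core, tree):
        _, core, entries = six_patient_core
        m = u.ccom(entries, core, tree, direction="symmetric")
        # carriers: 580–629 → {a,b,c,e,f}; 038.9 → {a,b,d,f}; 428.0 → {b,c}
        expected = np.array(
            [
                [5 / 6, 3 / 5, 2 / 5],
                [3 / 4, 4 / 6, 1 / 4],
                [2 / 2, 1 / 2, 2 / 6],
            ]
        )
        assert np.allclose(m.matrix, expected)

    def test_descendant_membership_counts_for_range_nodes(self, six_patient_core, tree):
        # patient f carries 599.0, a descendant of the 580–629 entry
        _, core, entries = six_patient_core
        m = u.ccom(entries, core, tree)
        assert m.matrix[0, 0] == pytest.approx(5 / 6)

    def test_always_coincident_entry_gives_conditional_one(self, six_patient_core, tree):
        _, core, entries = six_patient_core
        m = u.ccom(entries, core, tree)
        # every 428.0 carrier also carries 580–629
        assert m.value("428.0", "580–629") == 1.0

    def test_disjoint_entries_give_zero_both_ways(self, tree):
        patients = make_patients(
            {"a": [("038.9", 1)], "b": [("428.0", 1)]}
        )
        core = u.CoreZone(
            cluster=0, exemplar_id="a", patients=patients, mode="threshold", param=0.0
        )
        entries = [
            u.LCoPEntry(node="038.9", members=("038.9",), order=1),
            u.LCoPEntry(node="428.0", members=("428.0",), order=2),
        ]
        m = u.ccom(entries, core, tree)
        assert m.value("038.9", "428.0") == 0.0
        assert m.value("428.0", "038.9") == 0.0

    def test_order_directed_counts_precedence(self, six_patient_core, tree):
        _, core, entries = six_patient_core
        m = u.ccom(entries, core, tree, direction="order_directed")
        # among {a,b,f}: the genitourinary code precedes 038.9 in a, b and f
        assert m.value("580–629", "038.9") == pytest.approx(3 / 5)
        assert m.value("038.9", "580–629") == pytest.approx(0 / 4)

    def test_invariant_to_patient_ordering(self, six_patient_core, tree):
        patients, core, entries = six_patient_core
        rev = u.CoreZone(
            cluster=0,
            exemplar_id="f",
            patients=patients[::-1],
            mode="threshold",
            param=0.0,
        )
        m1 = u.ccom(entries, core, tree)
        m2 = u.ccom(entries, rev, tree)
        assert np.allclose(m1.matrix, m2.matrix)

    def test_missing_entry_row_zeroed_with_warning(self, six_patient_core, tree):
        _, core, entries = six_patient_core
        entries = entries + [u.LCoPEntry(node="715.90", members=("715.90",), order=4)]
        with pytest.warns(UserWarning, match="no core patient"):
            m = u.ccom(entries, core, tree)
        assert np.all(m.matrix[3] == 0)


def _uniform_ccom(nodes, value=0.5, diag=0.5):
    L = len(nodes)
    matrix = np.full((L, L), value)
    np.fill_diagonal(matrix, diag)
    return u.CCoM(nodes=nodes, matrix=matrix, core_size=10, direction="symmetric")


class TestIdentifyUD:
    def test_prefix_dominance_selects_first_three(self):
        """Entries mimicking the published cluster-2 split: the three
        earliest-order diseases dominate the circulatory and severe-sepsis
        entries, so the unifying diagnosis is the first three."""
        nodes = ["580–629", "038.9", "460–519", "390–459", "995.92"]
        entries = [
            u.LCoPEntry(node=n, members=(n,), order=o)
            for n, o in zip(nodes, [1, 2, 3, 5, 10])
        ]
        matrix = np.array(
            [
                [0.70, 0.60, 0.55, 0.90, 0.95],
                [0.55, 0.65, 0.50, 0.85, 0.90],
                [0.50, 0.45, 0.60, 0.80, 0.92],
                [0.40, 0.38, 0.35, 0.55, 0.60],
                [0.42, 0.40, 0.37, 0.50, 0.58],
            ]
        )
        m = u.CCoM(nodes=nodes, matrix=matrix, core_size=800, direction="symmetric")
        result = u.identify_ud(entries, m, rho=1.5)
        assert result.primaries == ["580–629", "038.9", "460–519"]
        assert result.complications == ["390–459", "995.92"]

    def test_single_entry_is_the_ud(self):
        entries = [u.LCoPEntry(node="038.9", members=("038.9",), order=1)]
        result = u.identify_ud(entries, _uniform_ccom(["038.9"]))
        assert result.primaries == ["038.9"] and result.complications == []

    def test_uniform_ccom_splits_after_first_by_tie_rule(self):
        nodes = ["a1", "b2", "c3"]
        entries = [
            u.LCoPEntry(node=n, members=(n,), order=o) for n, o in zip(nodes, [1, 2, 3])
        ]
        result = u.identify_ud(entries, _uniform_ccom(nodes), rho=1.5)
        assert not result.dominance.any()
        assert result.primaries == ["a1"]

    def test_raising_rho_never_creates_dominance(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(4)]
        matrix = rng.uniform(0.05, 0.95, size=(4, 4))
        m = u.CCoM(nodes=nodes, matrix=matrix, core_size=50, direction="symmetric")
        entries = [
            u.LCoPEntry(node=n, members=(n,), order=i + 1) for i, n in enumerate(nodes)
        ]
        prev = u.identify_ud(entries, m, rho=1.2).dominance
        for rho in (1.5, 2.0, 3.0, 10.0):
            cur = u.identify_ud(entries, m, rho=rho).dominance
            assert not (cur & ~prev).any()
            prev = cur

    def test_rho_must_exceed_one(self):
        entries = [u.LCoPEntry(node="038.9", members=("038.9",), order=1)]
        with pytest.raises(ValueError):
            u.identify_ud(entries, _uniform_ccom(["038.9"]), rho=1.0)
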
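"""Proofreading backend: edit semantics, replay, constraints, load harness."""

import numpy as np
import pytest

from vemtools.agglo import (
    AggloGraph,
    DuplicateEdgeError,
    EditRecord,
    MissingEdgeError,
    ReplayError,
    SelfEdgeError,
    UnknownSupervoxelError,
    constrained_agglomerate,
    effort_report,
    read_edit_log,
    replay,
    replay_load_test,
    write_edit_log,
)

from conftest import union_find_partition


def random_session(graph: AggloGraph, n_edits: int, seed: int) -> None:
    """Drive a random but always-applicable proofreading session."""
    rng = np.random.default_rng(seed)
    ids = sorted(graph.ids)
    for _ in range(n_edits):
        if graph.live_edges and rng.uniform() < 0.35:
            edges = sorted(graph.live_edges)
            a, b = edges[int(rng.integers(len(edges)))]
            graph.remove_edge(a, b, "tester")
        else:
            while True:
                a, b = rng.choice(ids, size=2, replace=False)
                if (min(a, b), max(a, b)) not in graph.live_edges:
                    break
            graph.add_edge(int(a), int(b), "tester")


class TestComponents:
    def test_isolated_supervoxel(self):
        g = AggloGraph([1, 2, 3])
        assert g.component_of(2) == {2}

    def test_chain(self):
        g = AggloGraph([1, 2, 3], [(1, 2), (2, 3)])
        assert g.component_of(2) == {1, 2, 3}

    def test_unknown_id(self):
        with pytest.raises(UnknownSupervoxelError):
            AggloGraph([1]).component_of(99)

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(0)
        n = 200
        edges = [tuple(sorted(rng.choice(n, 2, replace=False))) for _ in range(150)]
        g = AggloGraph(range(n), set(edges))
        oracle = union_find_partition(n, edges)
        groups_oracle = {}
        for i, r in enumerate(oracle):
            groups_oracle.setdefault(r, set()).add(i)
        for i in range(n):
            assert g.component_of(i) == groups_oracle[oracle[i]]

    def test_equivalence_relation(self):
        rng = np.random.default_rng(1)
        n = 60
        edges = {tuple(sorted(rng.choice(n, 2, replace=False))) for _ in range(40)}
        g = AggloGraph(range(n), edges)
        for s in rng.choice(n, 10, replace=False):
            comp = g.component_of(int(s))
            assert s in comp  # reflexive
            for t in comp:
                assert g.component_of(int(t)) == comp  # symmetric + transitive


class TestEdits:
    def test_add_remove_inverse(self):
        g = AggloGraph(range(6), [(0, 1), (2, 3)])
        before = g.partition()
        g.add_edge(1, 2)
        g.remove_edge(1, 2)
        assert g.partition() == before

    def test_error_taxonomy(self):
        g = AggloGraph(range(4), [(0, 1)])
        with pytest.raises(SelfEdgeError):
            g.add_edge(2, 2)
        with pytest.raises(DuplicateEdgeError):
            g.add_edge(0, 1)
        with pytest.raises(MissingEdgeError):
            g.remove_edge(2, 3)
        with pytest.raises(UnknownSupervoxelError):
            g.add_edge(0, 77)

    def test_component_sizes_after_join(self):
        g = AggloGraph(range(7), [(0, 1), (1, 2), (3, 4), (4, 5), (5, 6)])
        g.add_edge(2, 3)
        assert len(g.component_of(0)) == 7

    def test_base_edge_removal_expressible(self):
        g = AggloGraph(range(3), [(0, 1)])
        g.remove_edge(0, 1)
        assert g.component_of(0) == {0}
        g.add_edge(0, 1)
        assert g.component_of(0) == {0, 1}


class TestReplay:
    def test_empty_log_identity(self):
        g = AggloGraph(range(5), [(0, 1)])
        assert replay(g, []).partition() == g.partition()

    def test_random_session_replay_equals_live(self):
        base = AggloGraph(range(300), [(i, i + 1) for i in range(0, 298, 2)])
        live = AggloGraph(base.ids, base.base_edges)
        random_session(live, 1000, seed=5)
        replayed = replay(base, live.log)
        assert replayed.partition() == live.partition()

    def test_truncated_prefix_states(self):
        base = AggloGraph(range(50), [(i, i + 1) for i in range(0, 48, 3)])
        live = AggloGraph(base.ids, base.base_edges)
        fingerprints = []
        random_session(live, 120, seed=6)
        # rebuild each prefix from scratch and compare exact partitions
        reference = AggloGraph(base.ids, base.base_edges)
        for k, rec in enumerate(live.log, start=1):
            if rec.op == "add_edge":
                reference.add_edge(rec.a, rec.b)
            else:
                reference.remove_edge(rec.a, rec.b)
            if k % 20 == 0 or k == len(live.log):
                assert replay(base, live.log[:k]).partition() == reference.partition()

    def test_inapplicable_record_halts_with_seq(self):
        base = AggloGraph(range(4))
        log = [
            EditRecord(1, "add_edge", 0, 1),
            EditRecord(2, "remove_edge", 2, 3),  # never existed
        ]
        with pytest.raises(ReplayError) as e:
            replay(base, log)
        assert e.value.seq == 2

    def test_out_of_order_seq_halts(self):
        base = AggloGraph(range(4))
        log = [EditRecord(2, "add_edge", 0, 1), EditRecord(1, "add_edge", 1, 2)]
        with pytest.raises(ReplayError) as e:
            replay(base, log)
        assert e.value.seq == 1

    def test_log_file_roundtrip_bit_exact(self, tmp_path):
        g = AggloGraph(range(20), log_path=tmp_path / "edits.jsonl")
        random_session(g, 30, seed=7)
        on_disk = read_edit_log(tmp_path / "edits.jsonl")
        assert on_disk == g.log
        p = write_edit_log(g.log, tmp_path / "copy.jsonl")
        assert (tmp_path / "edits.jsonl").read_text() == p.read_text()

    def test_crash_consistency_from_truncated_file(self, tmp_path):
        base = AggloGraph(range(30), [(0, 1), (2, 3)])
        live = AggloGraph(base.ids, base.base_edges, log_path=tmp_path / "log.jsonl")
        random_session(live, 40, seed=8)
        lines = (tmp_path / "log.jsonl").read_text().splitlines()
        k = 17
        (tmp_path / "trunc.jsonl").write_text("\n".join(lines[:k]) + "\n")
        partial = replay(base, read_edit_log(tmp_path / "trunc.jsonl"))
        reference = replay(base, live.log[:k])
        assert partial.partition() == reference.partition()

    def test_replay_idempotent_as_new_base(self):
        base = AggloGraph(range(40), [(i, i + 1) for i in range(0, 38, 2)])
        live = AggloGraph(base.ids, base.base_edges)
        random_session(live, 100, seed=9)
        state = replay(base, live.log)
        rebased = AggloGraph(state.ids, state.live_edges)
        assert replay(rebased, []).partition() == state.partition()


class TestConstrainedAgglomeration:
    def test_no_nuclei_accepts_all(self):
        cands = [(0.9, 1, 2), (0.8, 2, 3), (0.7, 4, 5)]
        assert constrained_agglomerate([1, 2, 3, 4, 5], cands) == sorted(
            cands, key=lambda c: -c[0]
        )

    def test_chain_between_two_nuclei(self):
        # a(n1)-b-c(n2): only one of the two merges may happen
        accepted = constrained_agglomerate(
            [1, 2, 3], [(0.9, 1, 2), (0.9, 2, 3)], {1: 101, 3: 102}
        )
        assert accepted == [(0.9, 1, 2)]  # tie broken by lower min id

    def test_higher_score_wins(self):
        accepted = constrained_agglomerate(
            [1, 2, 3], [(0.5, 1, 2), (0.9, 2, 3)], {1: 10, 3: 11}
        )
        assert accepted == [(0.9, 2, 3)]

    @pytest.mark.parametrize("seed", range(10))
    def test_never_two_nuclei_per_component(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        nuclei = {int(i): 100 + int(i) for i in rng.choice(n, 8, replace=False)}
        cands = [
            (float(rng.uniform()), int(a), int(b))
            for a, b in rng.integers(0, n, (120, 2))
            if a != b
        ]
        accepted = constrained_agglomerate(range(n), cands, nuclei)
        part = union_find_partition(n, [(a, b) for _, a, b in accepted])
        comp_nuclei = {}
        for sv, nuc in nuclei.items():
            comp_nuclei.setdefault(part[sv], set()).add(nuc)
        assert all(len(s) <= 1 for s in comp_nuclei.values())


class TestEffortReport:
    def test_pure_split_fixing(self):
        log = [EditRecord(i + 1, "add_edge", i, i + 1) for i in range(5)]
        rep = effort_report(log, {"cell": set(range(6))})
        assert rep.iloc[0].merge_fixes == 0 and rep.iloc[0].split_fixes == 5

    def test_empty_log(self):
        rep = effort_report([], {"c1": {1}, "c2": {2}})
        assert (rep.merge_fixes == 0).all() and (rep.split_fixes == 0).all()

    def test_mixed_session_hand_enumeration(self):
        cells = {"A": {1, 2, 3}, "B": {10, 11}, "C": {20}}
        log = [
            EditRecord(1, "add_edge", 1, 2),      # A split fix
            EditRecord(2, "remove_edge", 2, 3),   # A merge fix
            EditRecord(3, "add_edge", 10, 11),    # B split fix
            EditRecord(4, "add_edge", 3, 20),     # touches A and C
            EditRecord(5, "remove_edge", 10, 11), # B merge fix
        ]
        rep = effort_report(log, cells).set_index("cell")
        assert rep.loc["A"].to_dict() == {"merge_fixes": 1, "split_fixes": 2}
        assert rep.loc["B"].to_dict() == {"merge_fixes": 1, "split_fixes": 1}
        assert rep.loc["C"].to_dict() == {"merge_fixes": 0, "split_fixes": 1}


class TestLoadHarness:
    def test_single_client_equals_replay(self):
        base = AggloGraph(range(60), [(i, i + 1) for i in range(0, 58, 2)])
        live = AggloGraph(base.ids, base.base_edges)
        random_session(live, 80, seed=11)
        table, final = replay_load_test(base, live.log, n_clients=1)
        assert final.partition() == replay(base, live.log).partition()
        assert set(table.op) <= {"add_edge", "remove_edge", "component"}

    @pytest.mark.parametrize("n_clients", [2, 4])
    def test_partition_independent_of_client_count(self, n_clients):
        base = AggloGraph(range(60), [(i, i + 1) for i in range(0, 58, 2)])
        live = AggloGraph(base.ids, base.base_edges)
        random_session(live, 80, seed=12)
        _, serial = replay_load_test(base, live.log, n_clients=1)
        _, parallel = replay_load_test(base, live.log, n_clients=n_clients)
        assert serial.partition() == parallel.partition()

    def test_empty_log_empty_table(self):
        table, final = replay_load_test(AggloGraph(range(5)), [], n_clients=3)
        assert table.empty
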
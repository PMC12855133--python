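import json

import pytest

from clinflow import (
    CANONICAL_ACTIVITIES,
    EventLog,
    LogGenConfig,
    WorkflowNet,
    discover_dfg,
    generate_log,
    log_conformance,
    sequence_model,
    token_replay,
)
from clinflow.eventlog import EmptyInputError

from conftest import make_trace
from replay_oracle import naive_replay


class TestSequenceModel:
    def test_four_stage_net_by_construction(self, pathway_net):
        assert len(pathway_net.transitions) == 4
        assert len(pathway_net.places) == 5
        assert len(pathway_net.arcs) == 8
        for i in range(4):
            assert pathway_net.inputs(f"t{i}") == [f"p{i}"]
            assert pathway_net.outputs(f"t{i}") == [f"p{i + 1}"]

    def test_minimal_single_activity_net(self):
        net = sequence_model(["CT-Sim"])
        assert len(net.transitions) == 1 and len(net.places) == 2

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            sequence_model(["A", "A"])

    def test_json_round_trip(self, pathway_net, tmp_path):
        path = pathway_net.to_json(tmp_path / "net.json")
        again = WorkflowNet.from_json(path)
        assert again.places == pathway_net.places
        assert again.transitions == pathway_net.transitions
        assert again.arcs == pathway_net.arcs


class TestTokenReplay:
    def test_conformant_trace_perfect_fitness(self, pathway_net):
        res = token_replay(list(CANONICAL_ACTIVITIES), pathway_net)
        assert (res.missing, res.remaining) == (0, 0)
        assert res.fitness == 1.0

    def test_skip_qa_hand_replay(self, pathway_net):
        res = token_replay(["CT-Sim", "Planning", "Treatment"], pathway_net)
        assert (res.produced, res.consumed, res.missing, res.remaining) == (4, 4, 1, 1)
        assert res.fitness == 0.75

    def test_repeated_firing_hand_replay(self, pathway_net):
        res = token_replay(["CT-Sim", "CT-Sim", "Planning", "QA Check", "Treatment"],
                           pathway_net)
        assert res.missing == 1
        assert res.fitness < 1.0

    def test_unmapped_activity_skipped_and_logged(self, pathway_net):
        res = token_replay(list(CANONICAL_ACTIVITIES) + ["Billing"], pathway_net)
        assert res.unmapped == ["Billing"]
        assert res.fitness == 1.0

    def test_strict_mode_penalizes_unmapped(self, pathway_net):
        res = token_replay(list(CANONICAL_ACTIVITIES) + ["Billing"], pathway_net,
                           strict=True)
        assert res.fitness < 1.0

    def test_fitness_one_iff_in_net_language(self, pathway_net):
        for labels in (
            list(CANONICAL_ACTIVITIES),
            ["CT-Sim", "Planning", "Treatment"],
            ["Planning", "CT-Sim", "QA Check", "Treatment"],
            list(CANONICAL_ACTIVITIES)[::-1],
        ):
            res = token_replay(labels, pathway_net)
            in_language = labels == list(CANONICAL_ACTIVITIES)
            assert (res.fitness == 1.0) == in_language
            assert 0.0 <= res.fitness <= 1.0

    def test_matches_independent_naive_oracle_on_seeded_corpus(self, pathway_net, tmp_path):
        """Dual-route check on >= 100 synthetic traces, tolerance 1e-9."""
        net_json = json.loads(pathway_net.to_json(tmp_path / "net.json").read_text())
        log = generate_log(LogGenConfig(n_cases=150, deviation_rate=0.5, seed=21))
        assert len(log) == 150
        for trace in log:
            ours = token_replay(trace, pathway_net)
            theirs = naive_replay(trace.activities, net_json)
            assert (ours.produced, ours.consumed, ours.missing, ours.remaining) == (
                theirs["p"], theirs["c"], theirs["m"], theirs["r"]), trace.case_id
            assert ours.fitness == pytest.approx(theirs["fitness"], abs=1e-9)


class TestLogConformance:
    def test_deviation_free_log_single_top_bin(self, pathway_net):
        log = generate_log(LogGenConfig(n_cases=40, deviation_rate=0.0, seed=3))
        result = log_conformance(log, pathway_net)
        assert result.mean_fitness == 1.0
        assert result.histogram["[0.90,1.00)"] == 40
        assert sum(result.histogram.values()) == 40

    def test_all_skip_log_mean(self, pathway_net):
        traces = [make_trace(f"c{i}", ["CT-Sim", "Planning", "Treatment"]) for i in range(40)]
        result = log_conformance(EventLog(traces=traces), pathway_net)
        assert result.mean_fitness == pytest.approx(0.75)
        assert all(r.fitness == 0.75 for r in result.per_case.values())

    @pytest.mark.parametrize("bin_width", [0.05, 0.1, 0.25])
    def test_histogram_conservation_any_bin_width(self, pathway_net, bin_width):
        log = generate_log(LogGenConfig(n_cases=120, deviation_rate=0.4, seed=9))
        result = log_conformance(log, pathway_net, bin_width=bin_width)
        assert sum(result.histogram.values()) == result.n_cases == 120

    def test_empty_log_raises(self, pathway_net):
        with pytest.raises(EmptyInputError):
            log_conformance(EventLog(), pathway_net)

    def test_mean_fitness_non_increasing_in_deviation_rate(self, pathway_net):
        means = [
            log_conformance(
                generate_log(LogGenConfig(n_cases=300, deviation_rate=d, seed=5)),
                pathway_net,
            ).mean_fitness
            for d in (0.0, 0.2, 0.4)
        ]
        assert means[0] > means[1] > means[2]


class TestDiscoverDfg:
    def test_deterministic_pathway_chain_weights(self):
        n = 25
        log = generate_log(LogGenConfig(n_cases=n, deviation_rate=0.0, seed=1))
        dfg = discover_dfg(log)
        for a, b in zip(CANONICAL_ACTIVITIES, CANONICAL_ACTIVITIES[1:]):
            assert dfg.arcs[(a, b)] == n
        assert dfg.start_counts["CT-Sim"] == n
        assert dfg.end_counts["Treatment"] == n

    def test_single_event_trace_no_arcs(self):
        log = EventLog(traces=[make_trace("c1", ["CT-Sim"])])
        dfg = discover_dfg(log)
        assert len(dfg.arcs) == 0
        assert dfg.start_counts["CT-Sim"] == 1 and dfg.end_counts["CT-Sim"] == 1

    def test_weights_equal_brute_force_pair_tally(self):
        log = generate_log(LogGenConfig(n_cases=60, deviation_rate=0.6, seed=13))
        dfg = discover_dfg(log)
        brute: dict = {}
        for trace in log:
            acts = trace.activities
            for i in range(len(acts) - 1):
                brute[(acts[i], acts[i + 1])] = brute.get((acts[i], acts[i + 1]), 0) + 1
        assert dict(dfg.arcs) == brute
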
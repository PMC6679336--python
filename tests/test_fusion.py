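import numpy as np
import pytest

from flockstream.fusion import (
    LabelledPair,
    RuleTable,
    apply_rules,
    default_rules,
    learn_rules,
    read_rules,
    records_to_frame,
    run_combined,
    write_rules,
)
from flockstream.online_kmeans import LEVELS, init_centroids
from flockstream.prototype import PrototypeModel, QuantisationScaling
from flockstream.signals import BEHAVIOURS

from conftest import make_stream


def passthrough_model(label="standing"):
    """A one-prototype model that always answers with the same label."""
    scaling = QuantisationScaling(lo=np.zeros(20), hi=np.ones(20))
    return PrototypeModel(
        prototypes=np.zeros((1, 20), dtype=int), labels=[label], scaling=scaling
    )


class TestDefaultRules:
    def test_unambiguous_cells(self):
        t = default_rules()
        assert apply_rules(t, "walking", "high") == "walking"
        assert apply_rules(t, "walking", "medium") == "walking"
        assert apply_rules(t, "walking", "low") == "walking"
        assert apply_rules(t, "standing", "high") == "walking"
        assert apply_rules(t, "standing", "medium") == "standing"
        assert apply_rules(t, "standing", "low") == "standing"
        assert apply_rules(t, "lying", "medium") == "lying"

    def test_conflict_cell_default_and_override(self):
        assert apply_rules(default_rules(), "lying", "low") == "lying"
        assert apply_rules(default_rules(lying_low="standing"), "lying", "low") == "standing"

    def test_unassigned_cell_falls_back_to_knn(self):
        assert apply_rules(default_rules(), "lying", "high") == "lying"

    def test_grid_is_total(self):
        t = default_rules()
        outputs = {apply_rules(t, b, l) for b in BEHAVIOURS for l in LEVELS}
        assert outputs <= set(BEHAVIOURS)


class TestRuleTableValidation:
    def test_missing_cell_rejected(self):
        m = default_rules().mapping.copy()
        del m[("lying", "low")]
        with pytest.raises(ValueError, match="missing cell"):
            RuleTable(mapping=m)

    def test_unknown_output_rejected(self):
        m = default_rules().mapping.copy()
        m[("lying", "low")] = "grazing"
        with pytest.raises(ValueError):
            RuleTable(mapping=m)


class TestLearnRules:
    def test_recovers_generating_table(self):
        table = default_rules()
        pairs = [
            LabelledPair(b, l, apply_rules(table, b, l))
            for b in BEHAVIOURS
            for l in LEVELS
            for _ in range(5)
        ]
        learned = learn_rules(pairs)
        for b in BEHAVIOURS:
            for l in LEVELS:
                assert apply_rules(learned, b, l) == apply_rules(table, b, l)

    def test_random_tables_round_trip(self, rng):
        for _ in range(20):
            mapping = {
                (b, l): BEHAVIOURS[rng.integers(3)] for b in BEHAVIOURS for l in LEVELS
            }
            table = RuleTable(mapping=mapping)
            pairs = [
                LabelledPair(b, l, mapping[(b, l)])
                for b in BEHAVIOURS
                for l in LEVELS
                for _ in range(3)
            ]
            learned = learn_rules(pairs)
            assert learned.mapping == mapping

    def test_constant_truth(self):
        pairs = [LabelledPair(b, l, "standing") for b in BEHAVIOURS for l in LEVELS]
        learned = learn_rules(pairs)
        assert all(v == "standing" for v in learned.mapping.values())

    def test_majority_vote(self):
        pairs = [LabelledPair("walking", "high", "walking")] * 3 + [
            LabelledPair("walking", "high", "standing")
        ] * 2
        assert learn_rules(pairs).mapping[("walking", "high")] == "walking"

    def test_sparse_cells_fall_back(self):
        pairs = [LabelledPair("walking", "high", "walking")] * 3
        learned = learn_rules(pairs, min_support=2)
        assert learned.mapping[("lying", "low")] is None
        assert apply_rules(learned, "lying", "low") == "lying"  # knn passthrough

    def test_tie_break_by_priority(self):
        pairs = [
            LabelledPair("lying", "medium", "standing"),
            LabelledPair("lying", "medium", "lying"),
        ]
        assert learn_rules(pairs).mapping[("lying", "medium")] == "standing"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            learn_rules([])


class TestRunCombined:
    def test_single_window_record(self):
        stream = make_stream(9.0)
        records, _ = run_combined(
            stream, passthrough_model(), init_centroids(priors=(5.0, 2.0, 0.5)), default_rules()
        )
        assert len(records) == 1
        r = records[0]
        assert set(r) == {"timestamp", "knn_label", "level", "mean_amag", "combined"}
        assert r["knn_label"] == "standing"

    def test_stuck_knn_high_activity_promotes_walking(self):
        # constant vigorous motion: KNN stuck on standing, levels high
        n = 16 * 30
        t = np.arange(n) / 16.0
        acc = np.column_stack([np.zeros(n), np.zeros(n), 1.0 + np.abs(np.sin(4 * np.pi * t))])
        stream_hi = type(make_stream(1.0))(t=t, acc=acc, gyro=np.zeros((n, 3)), rate_hz=16.0)
        state = init_centroids(priors=(5.0, 2.0, 0.5))
        records, _ = run_combined(stream_hi, passthrough_model("standing"), state, default_rules())
        assert all(r["level"] == "high" for r in records)
        assert all(r["combined"] == "walking" for r in records)

    def test_deterministic(self):
        stream = make_stream(60.0, seed=3)
        state = init_centroids(priors=(5.0, 2.0, 0.5))
        a, _ = run_combined(stream, passthrough_model(), state, default_rules())
        b, _ = run_combined(stream, passthrough_model(), state, default_rules())
        assert a == b

    def test_records_frame_shape(self):
        stream = make_stream(40.0)
        records, final = run_combined(
            stream, passthrough_model(), init_centroids(priors=(5.0, 2.0, 0.5)), default_rules()
        )
        df = records_to_frame(records)
        assert len(df) == 4
        assert len(final.history) == 4


class TestRulesIO:
    @pytest.mark.parametrize("table", [default_rules(), default_rules(lying_low="standing")])
    def test_round_trip(self, tmp_path, table):
        p = tmp_path / "rules.txt"
        write_rules(table, p)
        back = read_rules(p)
        assert back.mapping == table.mapping
        assert back.fallback == table.fallback
        assert back.provenance == table.provenance

    def test_file_has_nine_cells(self, tmp_path):
        p = tmp_path / "rules.txt"
        write_rules(default_rules(), p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 1 + 9 + 2  # header, cells, fallback, provenance
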
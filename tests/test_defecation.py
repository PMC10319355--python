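"""DMP rhythm statistics: parsing, cycle arithmetic, frequency ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormquant import (
    Event,
    EventLog,
    EventLogSpec,
    aboc_frequency,
    cycle_lengths,
    expulsion_frequency,
    generate_event_log,
    mean_cycle_length,
    parse_boris_csv,
    summarize_group,
)
from wormquant.defecation import summarize_animal, write_boris_csv
from wormquant.errors import EventLogError


def make_log(pboc, aboc=(), exp=(), animal="w1"):
    events = (
        [Event(t, "pBoc", animal) for t in pboc]
        + [Event(t, "aBoc", animal) for t in aboc]
        + [Event(t, "Exp", animal) for t in exp]
    )
    events.sort(key=lambda e: (e.time_s, {"pBoc": 0, "aBoc": 1, "Exp": 2}[e.label]))
    return EventLog(animal=animal, events=tuple(events))


class TestParsing:
    def test_toy_csv_single_animal(self, tmp_path):
        csv = "Observation id,Time,Behavior\nw1,10.0,pBoc\nw1,60.0,pboc\nw1,45.0,aBoc\n"
        path = tmp_path / "toy.csv"
        path.write_text(csv)
        logs = parse_boris_csv(path)
        assert len(logs) == 1
        assert [e.label for e in logs[0].events] == ["pBoc", "aBoc", "pBoc"]
        assert [e.time_s for e in logs[0].events] == [10.0, 45.0, 60.0]

    def test_two_observation_ids_give_two_logs(self, tmp_path):
        csv = "Observation id,Time,Behavior\na,0,pBoc\nb,0,pBoc\na,50,pBoc\nb,55,pBoc\n"
        path = tmp_path / "two.csv"
        path.write_text(csv)
        logs = parse_boris_csv(path)
        assert sorted(log.animal for log in logs) == ["a", "b"]

    def test_unknown_labels_skipped_with_warning(self, tmp_path):
        csv = "Observation id,Time,Behavior\nw,0,pBoc\nw,10,grooming\nw,50,pBoc\n"
        path = tmp_path / "unk.csv"
        path.write_text(csv)
        with pytest.warns(UserWarning, match="unknown behavior"):
            logs = parse_boris_csv(path)
        assert logs[0].count("pBoc") == 2

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("foo,bar\n1,2\n")
        with pytest.raises(EventLogError, match="missing required columns"):
            parse_boris_csv(path)

    def test_unparseable_time_reports_row(self, tmp_path):
        path = tmp_path / "bad_time.csv"
        path.write_text("Observation id,Time,Behavior\nw,abc,pBoc\n")
        with pytest.raises(EventLogError, match="row"):
            parse_boris_csv(path)

    def test_round_trip_preserves_events(self, tmp_path):
        logs = [
            generate_event_log(EventLogSpec(n_cycles=12, seed=i, animal=f"w{i}"))[0]
            for i in range(3)
        ]
        path = tmp_path / "rt.csv"
        write_boris_csv(logs, path)
        parsed = parse_boris_csv(path)
        assert len(parsed) == 3
        for orig, back in zip(sorted(logs, key=lambda x: x.animal), parsed):
            assert [e.time_s for e in orig.events] == [e.time_s for e in back.events]
            assert [e.label for e in orig.events] == [e.label for e in back.events]


class TestCycleArithmetic:
    @pytest.mark.parametrize(
        "pboc, expected",
        [([0, 50, 100], [50, 50]), ([0, 45, 100], [45, 55])],
    )
    def test_successive_differences(self, pboc, expected):
        assert cycle_lengths(make_log(pboc)).tolist() == expected

    def test_single_pboc_rejected(self):
        with pytest.raises(EventLogError, match="pBoc"):
            cycle_lengths(make_log([10.0]))

    def test_mean_of_first_ten_cycles(self):
        log = make_log(np.cumsum([0] + list(range(40, 52))))  # 12 cycles 40..51
        assert mean_cycle_length(log) == pytest.approx(np.mean(range(40, 50)))

    def test_arithmetic_sequence_mean(self):
        log = make_log(np.cumsum([0] + list(range(40, 50))))
        assert mean_cycle_length(log) == pytest.approx(44.5)

    def test_insufficient_cycles_rejected(self):
        log = make_log([0, 50, 100, 150])
        with pytest.raises(EventLogError, match="10"):
            mean_cycle_length(log, n_cycles=10)

    def test_mean_ignores_cycles_beyond_the_first_ten(self):
        base = np.cumsum([0.0] + [50.0] * 10)
        log_a = make_log(base)
        log_b = make_log(np.concatenate([base, base[-1] + np.cumsum([200.0, 300.0])]))
        assert mean_cycle_length(log_a) == mean_cycle_length(log_b)

    def test_generated_log_intervals_recovered_exactly(self):
        log, intervals = generate_event_log(
            EventLogSpec(mean_period_s=45.0, period_sd_s=5.0, n_cycles=12, seed=8)
        )
        assert np.allclose(cycle_lengths(log), intervals)
        assert mean_cycle_length(log) == pytest.approx(np.mean(intervals[:10]))

    @given(st.lists(st.floats(0.5, 200.0), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_interval_sum_conservation(self, intervals):
        pboc = np.concatenate([[0.0], np.cumsum(intervals)])
        log = make_log(pboc)
        assert np.sum(cycle_lengths(log)) == pytest.approx(pboc[-1] - pboc[0], abs=1e-8)


class TestFrequencies:
    def test_ratio_of_counts(self):
        log = make_log(np.arange(0, 501, 50), aboc=[25, 75, 125, 175, 225])
        assert aboc_frequency(log) == pytest.approx(5 / 11)

    def test_equal_counts_give_unity(self):
        log = make_log([0, 50], aboc=[20, 70], exp=[45, 95])
        assert aboc_frequency(log) == 1.0
        assert expulsion_frequency(log) == 1.0

    def test_binomial_recovery_at_200_cycles(self):
        log, _ = generate_event_log(
            EventLogSpec(n_cycles=200, aboc_probability=0.8, seed=13)
        )
        n_pboc = 201
        se = np.sqrt(0.8 * 0.2 / 200)
        assert abs(aboc_frequency(log) - 0.8 * 200 / n_pboc) <= 3 * se

    def test_time_shift_invariance(self):
        log, _ = generate_event_log(EventLogSpec(n_cycles=15, seed=3))
        shifted = EventLog(
            animal=log.animal,
            events=tuple(
                Event(e.time_s + 123.5, e.label, e.animal) for e in log.events
            ),
        )
        assert aboc_frequency(shifted) == aboc_frequency(log)
        assert expulsion_frequency(shifted) == expulsion_frequency(log)
        assert np.allclose(cycle_lengths(shifted), cycle_lengths(log))

    def test_simultaneous_pboc_sorts_first(self):
        log = make_log([0, 50, 100], aboc=[50.0])
        labels_at_50 = [e.label for e in log.events if e.time_s == 50.0]
        assert labels_at_50 == ["pBoc", "aBoc"]


class TestGroupSummary:
    def test_single_animal_collapses_quantiles(self):
        log, _ = generate_event_log(EventLogSpec(n_cycles=10, seed=1, animal="solo"))
        table = summarize_group([log])
        row = table[table.statistic == "mean_cycle_length_s"].iloc[0]
        assert row["min"] == row.q25 == row["median"] == row.q75 == row["max"]

    def test_known_quantiles_one_to_five(self):
        logs = []
        for i, mean in enumerate([1, 2, 3, 4, 5]):
            pboc = np.cumsum([0.0] + [float(mean)] * 10)
            logs.append(
                EventLog(
                    animal=f"w{i}",
                    condition="wt",
                    events=tuple(Event(t, "pBoc", f"w{i}") for t in pboc),
                )
            )
        table = summarize_group(logs)
        row = table[table.statistic == "mean_cycle_length_s"].iloc[0]
        assert (row.q25, row["median"], row.q75) == (2.0, 3.0, 4.0)
        assert (row["min"], row["max"]) == (1.0, 5.0)

    def test_two_condition_difference_recovered(self):
        logs = []
        cmap = {}
        for i in range(30):
            for cond, mean in (("wt", 50.0), ("mut", 60.0)):
                animal = f"{cond}{i}"
                log, _ = generate_event_log(
                    EventLogSpec(mean_period_s=mean, period_sd_s=5.0, n_cycles=10,
                                 seed=1000 + i * 2 + (cond == "mut"), animal=animal)
                )
                logs.append(log)
                cmap[animal] = cond
        table = summarize_group(logs, condition_map=cmap)
        cyc = table[table.statistic == "mean_cycle_length_s"].set_index("condition")
        diff = cyc.loc["mut", "mean"] - cyc.loc["wt", "mean"]
        se = np.sqrt(2) * (5.0 / np.sqrt(10)) / np.sqrt(30)
        assert abs(diff - 10.0) <= 3 * se

    def test_empty_group_rejected(self):
        with pytest.raises(EventLogError):
            summarize_group([])

    def test_summary_dataclass_consistency(self):
        log, intervals = generate_event_log(EventLogSpec(n_cycles=12, seed=5))
        s = summarize_animal(log)
        assert s.mean_cycle_length_s == pytest.approx(np.mean(intervals[:10]))
        assert len(s.cycle_lengths_s) == 12
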
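"""Bout detection: parsing, thresholds, state machine vs brute force."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from chronest import (
    SimulationConfig,
    gen_ambient_trace,
    gen_nest_temperature,
)
from chronest.bout_detect import (
    Bout,
    BoutSeries,
    TemperatureTrace,
    Thresholds,
    TraceError,
    april_day,
    derive_thresholds,
    detect_bouts,
    detect_incubation_start,
    detect_onsets_for_trace,
    extract_daily_onsets,
    infer_accuracy,
    parse_logger_export,
    _scan_boundaries,
)
from conftest import make_trace


def oracle_boundaries(temp, amb, drop, rise):
    """Brute-force boundary scan: every running extremum recomputed
    from scratch over the current bout's slice (no incremental state)."""
    boundaries = []
    state = "on"
    start = 0
    k = 1
    n = len(temp)
    while k < n:
        if state == "on":
            window = temp[start:k]
            i_ref = start + int(np.argmax(window))
            ref = temp[i_ref]
            if ref - temp[k] > drop and (temp[k] - amb[k]) < (ref - amb[i_ref]):
                j = max(k - 1, start + 1)
                boundaries.append(j)
                state = "off"
                start = j
        else:
            window = temp[start:k]
            ref = np.min(window)
            if temp[k] - ref > rise:
                j = max(k - 1, start + 1)
                boundaries.append(j)
                state = "on"
                start = j
        k += 1
    return boundaries


class TestParse:
    def test_wellformed_file_roundtrips(self, tmp_path):
        times = pd.date_range("2021-04-10", periods=480, freq="3min")
        df = pd.DataFrame({"datetime": times, "temperature": 35.0})
        p = tmp_path / "nest.csv"
        df.to_csv(p, index=False)
        trace = parse_logger_export(p)
        assert len(trace.times) == 480

    def test_duplicate_timestamp_rejected_with_line_number(self, tmp_path):
        times = list(pd.date_range("2021-04-10", periods=5, freq="3min"))
        times[3] = times[2]
        p = tmp_path / "nest.csv"
        pd.DataFrame({"datetime": times, "temperature": 35.0}).to_csv(p, index=False)
        with pytest.raises(TraceError, match="line"):
            parse_logger_export(p)

    def test_unparseable_rows_listed(self, tmp_path):
        p = tmp_path / "nest.csv"
        p.write_text("datetime,temperature\n2021-04-10T00:00,35.0\nnot-a-date,35.0\n")
        with pytest.raises(TraceError, match=r"lines \[3\]"):
            parse_logger_export(p)

    def test_accuracy_inferred_from_minimal_step(self):
        assert infer_accuracy(np.array([35.0, 34.5, 35.0])) == 0.5
        assert infer_accuracy(np.array([35.0, 35.0625, 35.5])) == 0.0625


class TestIncubationStart:
    def _two_phase_trace(self, cold_nights, total_days=5):
        times = pd.date_range("2021-04-10", periods=total_days * 480, freq="3min")
        amb = np.full(len(times), 10.0)
        temp = amb.copy()
        switch = pd.Timestamp("2021-04-10") + pd.Timedelta(days=cold_nights - 1, hours=21)
        temp[np.asarray(times >= switch)] = 20.0
        return TemperatureTrace("T", times, temp, 0.0625, amb)

    def test_trace_at_ambient_never_starts(self):
        trace = self._two_phase_trace(cold_nights=99)
        assert detect_incubation_start(trace) is None

    def test_switch_on_night_three_detected(self):
        # nights 1-2 at ambient, warm from the evening before day 3
        trace = self._two_phase_trace(cold_nights=3)
        assert detect_incubation_start(trace) == dt.date(2021, 4, 13)

    def test_programmed_starts_recovered_across_seeds(self):
        hits = 0
        for seed in range(50):
            cfg = SimulationConfig(seed=seed)
            start_day = 11 + seed % 3
            ambient = gen_ambient_trace(6, seed, start=dt.date(2021, 4, 10))
            trace = gen_nest_temperature(
                {}, ambient, cfg, incubation_start=dt.date(2021, 4, start_day)
            )
            if detect_incubation_start(trace) == dt.date(2021, 4, start_day):
                hits += 1
        assert hits >= 45  # >= 90 % exact


class TestThresholds:
    def test_constant_night_floors_at_half_degree(self):
        temp = np.full(480, 35.0)
        trace = make_trace(temp, start="2021-04-12 00:00")
        th = derive_thresholds(trace, dt.date(2021, 4, 12))
        assert th.drop == 0.5

    def test_noisy_night_raises_threshold_above_floor(self):
        rng = np.random.default_rng(0)
        temp = 35.0 + rng.normal(0, 0.4, 480 * 2)
        trace = make_trace(temp, start="2021-04-11 12:00")
        th = derive_thresholds(trace, dt.date(2021, 4, 12))
        # oracle: the empirical night-difference quantile itself
        night = trace.temp[trace.window(pd.Timestamp("2021-04-11 21:00"),
                                        pd.Timestamp("2021-04-12 05:00"))]
        q = np.quantile(np.abs(np.diff(night)), 0.95)
        assert th.drop > 0.5
        assert th.drop == pytest.approx(max(0.5, q))

    def test_thresholds_deterministic(self, one_day_trace):
        _, trace = one_day_trace
        a = derive_thresholds(trace, dt.date(2021, 4, 12))
        b = derive_thresholds(trace, dt.date(2021, 4, 12))
        assert a == b

    def test_sparse_night_falls_back_flagged(self):
        temp = np.full(100, 35.0)
        trace = make_trace(temp, start="2021-04-12 08:00")
        th = derive_thresholds(trace, dt.date(2021, 4, 12))
        assert th.fallback


class TestDetectBouts:
    def test_flat_day_is_single_on_bout(self):
        temp = np.full(480, 35.0)
        trace = make_trace(temp, start="2021-04-12 00:00")
        th = Thresholds(0.5, 0.5, dt.date(2021, 4, 12))
        bouts = detect_bouts(trace, th, dt.date(2021, 4, 12))
        assert len(bouts) == 1 and bouts[0].label == "on"

    def test_subthreshold_dip_ignored(self):
        temp = np.full(480, 35.0)
        temp[100:104] = 34.7  # 0.3 degC dip, threshold 0.5
        trace = make_trace(temp, start="2021-04-12 00:00")
        th = Thresholds(0.5, 0.5, dt.date(2021, 4, 12))
        bouts = detect_bouts(trace, th, dt.date(2021, 4, 12))
        assert len(bouts) == 1

    def test_programmed_offbout_found_within_one_sample(self, one_day_trace):
        _, trace = one_day_trace
        date = dt.date(2021, 4, 12)
        th = derive_thresholds(trace, date)
        bouts = detect_bouts(trace, th, date)
        offs = [b for b in bouts if b.label == "off"]
        assert offs
        first = offs[0]
        prog_start = pd.Timestamp("2021-04-12 05:30")
        assert abs((first.start - prog_start).total_seconds()) <= 180

    def test_day_partition_conserved(self, one_day_trace):
        _, trace = one_day_trace
        date = dt.date(2021, 4, 12)
        th = derive_thresholds(trace, date)
        bouts = detect_bouts(trace, th, date)
        total = sum((b.duration for b in bouts), pd.Timedelta(0))
        day_mask = trace.window(pd.Timestamp(date), pd.Timestamp(date) + pd.Timedelta(days=1))
        span = trace.times[day_mask][-1] - trace.times[day_mask][0]
        assert total == span
        for a, b in zip(bouts, bouts[1:]):
            assert a.end == b.start and a.label != b.label


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(50))
    def test_state_machine_matches_bruteforce_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 201))
        temp = 35.0 + np.cumsum(rng.normal(0, 0.6, n))
        amb = 10.0 + np.cumsum(rng.normal(0, 0.1, n))
        drop = float(rng.uniform(0.5, 3.0))
        rise = float(rng.uniform(0.5, 3.0))
        assert _scan_boundaries(temp, amb, drop, rise) == oracle_boundaries(
            temp, amb, drop, rise
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_raising_drop_threshold_never_adds_offbouts(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 300
        temp = 35.0 + np.cumsum(rng.normal(0, 0.5, n))
        amb = np.full(n, 10.0)
        counts = [
            len([b for b in _scan_boundaries(temp, amb, drop, 0.5)])
            for drop in (0.5, 1.0, 2.0, 4.0)
        ]
        n_off = [(c + 1) // 2 for c in counts]
        assert all(a >= b for a, b in zip(n_off, n_off[1:]))


class TestExtractOnsets:
    def _series(self, bouts, date=dt.date(2021, 4, 12)):
        s = BoutSeries("T")
        s.add_day(date, bouts)
        return s

    def test_first_offbout_after_night_sit_is_onset(self):
        d = pd.Timestamp("2021-04-12")
        bouts = [
            Bout(d, d + pd.Timedelta(hours=5.5), "on"),
            Bout(d + pd.Timedelta(hours=5.5), d + pd.Timedelta(hours=5.7), "off"),
            Bout(d + pd.Timedelta(hours=5.7), d + pd.Timedelta(hours=24), "on"),
        ]
        brood = {"female_id": "F1", "brood_id": "B1", "nest_box": "N1",
                 "year": 2021, "incubation_start": 5}
        onsets, qc = extract_daily_onsets(self._series(bouts), brood)
        assert len(onsets) == 1
        assert onsets["onset"].iloc[0] == pytest.approx(5.5)
        assert onsets["breeding_day"].iloc[0] == april_day(dt.date(2021, 4, 12)) - 18
        assert onsets["stage"].iloc[0] == "incubation"

    def test_all_day_on_bout_yields_no_record(self):
        d = pd.Timestamp("2021-04-12")
        bouts = [Bout(d, d + pd.Timedelta(hours=24), "on")]
        brood = {"incubation_start": 5}
        onsets, qc = extract_daily_onsets(self._series(bouts), brood)
        assert onsets.empty
        assert qc["reason"].iloc[0] == "no off-bout"

    def test_dates_past_max_chick_day_excluded(self):
        d = pd.Timestamp("2021-04-12")
        bouts = [
            Bout(d, d + pd.Timedelta(hours=5), "on"),
            Bout(d + pd.Timedelta(hours=5), d + pd.Timedelta(hours=6), "off"),
            Bout(d + pd.Timedelta(hours=6), d + pd.Timedelta(hours=24), "on"),
        ]
        brood = {"incubation_start": april_day(dt.date(2021, 3, 5)), "hatch_date": None}
        onsets, qc = extract_daily_onsets(self._series(bouts), brood)
        assert onsets.empty
        assert (qc["reason"] == "past max chick day").all()


class TestRoundTrip:
    def test_programmed_onsets_recovered(self):
        """>= 95 % of programmed departures recovered within 3 minutes."""
        recovered, total = 0, 0
        for nest in range(10):
            seed = 200 + nest
            rng = np.random.default_rng(seed)
            cfg = SimulationConfig(seed=seed)
            ambient = gen_ambient_trace(5, seed, start=dt.date(2021, 4, 10))
            sched, prog = {}, {}
            for d in range(1, 4):
                date = dt.date(2021, 4, 10 + d)
                onset = float(rng.uniform(4.8, 6.5))
                sched[date] = [(onset, 12.0), (onset + 2.5, 15.0)]
                prog[april_day(date)] = onset
            trace = gen_nest_temperature(sched, ambient, cfg,
                                         incubation_start=dt.date(2021, 4, 11))
            brood = {"female_id": "F", "brood_id": "B", "nest_box": "N",
                     "year": 2021, "incubation_start": 8}
            onsets, _ = detect_onsets_for_trace(trace, brood)
            det = dict(zip(onsets["date"], onsets["onset"]))
            for aday, t in prog.items():
                total += 1
                if aday in det and abs(det[aday] - t) * 60 <= 3.0:
                    recovered += 1
        assert recovered / total >= 0.95

    def test_requantising_to_coarse_accuracy_shifts_onsets_at_most_one_sample(self):
        seed = 77
        rng = np.random.default_rng(seed)
        cfg = SimulationConfig(seed=seed, logger_accuracy=0.0625)
        ambient = gen_ambient_trace(5, seed, start=dt.date(2021, 4, 10))
        sched = {}
        for d in range(1, 4):
            date = dt.date(2021, 4, 10 + d)
            onset = float(rng.uniform(5.0, 6.0))
            sched[date] = [(onset, 12.0), (onset + 3.0, 15.0)]
        fine = gen_nest_temperature(sched, ambient, cfg,
                                    incubation_start=dt.date(2021, 4, 11))
        coarse = TemperatureTrace(
            fine.nest_id, fine.times, np.round(fine.temp / 0.5) * 0.5, 0.5, fine.ambient
        )
        brood = {"female_id": "F", "brood_id": "B", "nest_box": "N",
                 "year": 2021, "incubation_start": 8}
        on_f, _ = detect_onsets_for_trace(fine, brood)
        on_c, _ = detect_onsets_for_trace(coarse, brood)
        merged = on_f.merge(on_c, on="date", suffixes=("_f", "_c"))
        assert len(merged) >= 2
        assert (np.abs(merged["onset_f"] - merged["onset_c"]) * 60 <= 3.0 + 1e-9).all()

    def test_trace_gap_invalidates_date(self):
        cfg = SimulationConfig(seed=12)
        ambient = gen_ambient_trace(5, 12, start=dt.date(2021, 4, 10))
        sched = {dt.date(2021, 4, 12): [(5.5, 12.0)]}
        trace = gen_nest_temperature(sched, ambient, cfg,
                                     incubation_start=dt.date(2021, 4, 11))
        # remove 30 min around 03:00 on the 12th
        hole = trace.window(pd.Timestamp("2021-04-12 03:00"), pd.Timestamp("2021-04-12 03:30"))
        keep = ~np.asarray(hole)
        gappy = TemperatureTrace("T", trace.times[keep], trace.temp[keep],
                                 trace.accuracy, trace.ambient[keep])
        brood = {"female_id": "F", "brood_id": "B", "nest_box": "N",
                 "year": 2021, "incubation_start": 8}
        onsets, qc = detect_onsets_for_trace(gappy, brood)
        assert 12 not in set(onsets["date"])
        assert any(qc["reason"] == "gap in trace")
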
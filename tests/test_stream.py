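import numpy as np
import pytest
from collections import Counter, deque
from hypothesis import given, strategies as st

import emgeca as eg
from emgeca.errors import ValidationError
from emgeca.stream import (REST, SerialFrameFormatter, majority_vote,
                           transition_count)


def simulate_votes(raw_labels, W, tie_rule="keep_previous"):
    """Independent vote-buffer simulation on a constructed label sequence."""
    buf, out, prev = deque(maxlen=W), [], None
    for lab in raw_labels:
        buf.append(lab)
        counts = Counter(buf)
        top = max(counts.values())
        tied = [c for c, n in counts.items() if n == top]
        if len(tied) == 1:
            v = tied[0]
        elif tie_rule == "keep_previous" and prev in tied:
            v = prev
        else:
            v = next(b for b in reversed(buf) if b in tied)
        out.append(v)
        prev = v
    return out


class TestMajorityVote:
    def test_strict_majority(self):
        assert majority_vote([1, 1, 2, 1, 1]) == 1

    def test_single_vote_identity(self):
        assert majority_vote([7], "keep_previous") == 7
        assert majority_vote([7], "most_recent") == 7

    def test_tie_rules(self):
        votes = [1, 1, 2, 2]
        assert majority_vote(votes, "keep_previous", previous=2) == 2
        assert majority_vote(votes, "most_recent") == 2
        assert majority_vote(votes, "keep_previous", previous=1) == 1
        # previous not among tied classes -> most recent tied class
        assert majority_vote(votes, "keep_previous", previous=9) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            majority_vote([])

    @given(labels=st.lists(st.integers(0, 3), min_size=1, max_size=40),
           w=st.sampled_from([1, 3, 5, 10]))
    def test_matches_buffer_simulation(self, labels, w):
        expected = simulate_votes(labels, w)
        buf, prev, got = deque(maxlen=w), None, []
        for lab in labels:
            buf.append(lab)
            v = majority_vote(buf, "keep_previous", previous=prev)
            got.append(v)
            prev = v
        assert got == expected


class TestVoteSmoothing:
    def test_isolated_errors_removed(self):
        # 200 steps of class A with 5 isolated single-step B errors, W=100
        raw = [0] * 200
        for i in (30, 70, 110, 150, 190):
            raw[i] = 1
        voted = simulate_votes(raw, 100)
        assert transition_count(raw) == 10
        assert voted == [0] * 200
        assert transition_count(voted) == 0

    def test_error_runs_below_half_window_never_flip(self):
        for W in (10, 50, 100):
            run = int(np.ceil(W / 2)) - 1
            raw = [0] * W + [1] * run + [0] * W
            voted = simulate_votes(raw, W)
            assert set(voted[W:]) == {0}

    def test_w1_is_identity(self):
        rng = np.random.default_rng(0)
        raw = list(rng.integers(0, 4, size=100))
        assert simulate_votes(raw, 1) == raw

    def test_transitions_non_increasing_in_w(self):
        rng = np.random.default_rng(1)
        base = np.repeat(rng.integers(0, 4, size=10), 50)
        noisy = base.copy()
        flips = rng.choice(len(noisy), size=60, replace=False)
        noisy[flips] = rng.integers(0, 4, size=60)
        counts = [transition_count(simulate_votes(list(noisy), W))
                  for W in (10, 50, 100)]
        assert counts[0] >= counts[1] >= counts[2]


class TestCalibration:
    def test_zero_rest_gives_zero_baseline(self):
        rest = eg.EmgRecording(np.zeros((3000, 4)), 1000.0, -1)
        bl = eg.calibrate_baseline(rest)
        assert bl.level == 0.0
        assert bl.absolute_threshold(3.0) == 0.0

    def test_deterministic_and_linear(self):
        p = eg.desk_protocol(duration_s=3.0, reps_range=(1, 1), subject_seed=0)
        rest = eg.rest_recording(p, 5)
        a = eg.calibrate_baseline(rest)
        b = eg.calibrate_baseline(eg.rest_recording(p, 5))
        assert np.array_equal(a.channel_mean, b.channel_mean)
        doubled = eg.EmgRecording(2 * rest.samples, rest.fs, -1)
        c = eg.calibrate_baseline(doubled)
        assert c.absolute_threshold(3.0) == pytest.approx(
            2 * a.absolute_threshold(3.0), rel=1e-9)

    def test_short_rest_rejected(self):
        rest = eg.EmgRecording(np.zeros((500, 4)), 1000.0, -1)
        with pytest.raises(ValidationError):
            eg.calibrate_baseline(rest)


@pytest.fixture(scope="module")
def stream_setup(tmp_path_factory):
    p = eg.desk_protocol(duration_s=6.0, reps_range=(2, 3), n_gestures=2,
                         subject_seed=31)
    recs = eg.synth_session(p)
    envs = [eg.extract_envelope(r) for r in recs]
    ws = eg.split_windows(eg.segment_session(envs))
    tm = eg.train_model(eg.compact_spec(ws.window_len, 8, 2),
                        ws, eg.desk_train_config(seed=0, epochs=5))
    causal = eg.EnvelopeConfig(zero_phase=False)
    baseline = eg.calibrate_baseline(eg.rest_recording(p, 404), causal)
    return p, recs, tm, causal, baseline


class TestReplay:
    def test_pure_rest_emits_nothing(self, stream_setup):
        p, recs, tm, causal, baseline = stream_setup
        rest = eg.rest_recording(p, 77)
        cmds, trace = eg.replay_session(rest, tm, eg.StreamConfig(), causal, baseline)
        assert cmds == []
        assert (trace["raw"] == REST).all()

    def test_active_recording_emits_commands(self, stream_setup):
        p, recs, tm, causal, baseline = stream_setup
        sink = SerialFrameFormatter()
        cmds, trace = eg.replay_session(recs[1], tm, eg.StreamConfig(vote_window_W=10),
                                        causal, baseline, sink=sink)
        assert len(cmds) >= 1
        assert all(0 < c.vote_fraction <= 1 for c in cmds)
        assert len(sink.frames) == len(cmds)
        header, cid, chk = sink.frames[0]
        assert header == 0xAA and chk == 0xAA ^ cid
        # trace raw and voted sequences have equal length
        assert len(trace["raw"]) == len(trace["voted"])

    def test_replay_deterministic(self, stream_setup):
        p, recs, tm, causal, baseline = stream_setup
        cfg = eg.StreamConfig(vote_window_W=10)
        _, t1 = eg.replay_session(recs[0], tm, cfg, causal, baseline)
        _, t2 = eg.replay_session(recs[0], tm, cfg, causal, baseline)
        assert t1.equals(t2)

    def test_causality_by_truncation(self, stream_setup):
        # the first half of the trace is unchanged if the future is removed
        p, recs, tm, causal, baseline = stream_setup
        cfg = eg.StreamConfig(vote_window_W=10)
        _, full = eg.replay_session(recs[1], tm, cfg, causal, baseline)
        half_rec = eg.EmgRecording(recs[1].samples[:recs[1].n_samples // 2],
                                   recs[1].fs, recs[1].gesture_label)
        _, half = eg.replay_session(half_rec, tm, cfg, causal, baseline)
        n = len(half)
        assert half.equals(full.iloc[:n].reset_index(drop=True))

    def test_zero_phase_config_rejected(self, stream_setup):
        p, recs, tm, _, baseline = stream_setup
        with pytest.raises(ValidationError):
            eg.replay_session(recs[0], tm, eg.StreamConfig(),
                              eg.EnvelopeConfig(zero_phase=True), baseline)

    def test_vote_buffer_bounded(self, stream_setup):
        p, recs, tm, causal, baseline = stream_setup
        wl = int(round(300 * p.fs / 1000))
        state = eg.init_stream(wl, p.n_channels, baseline)
        cfg = eg.StreamConfig(vote_window_W=3)
        rng = np.random.default_rng(0)
        block = recs[1].samples[2000:2100]
        for _ in range(12):
            eg.stream_step(state, block, tm, cfg, causal, p.fs)
        assert len(state.votes) <= 3
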
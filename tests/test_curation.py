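import numpy as np
import pytest

from asrcurate.audioseg import AudioSignal, SegmenterConfig, TimeSpan
from asrcurate.curation import (
    IterateConfig,
    IterationRecord,
    MockBackend,
    OracleBackend,
    SegmentAudio,
    SegmentStatus,
    curate_pass,
    iterate,
    make_mock_backend,
)
from asrcurate.metrics import corpus_wer
from asrcurate.synthdata import (
    DEFAULT_VOCABULARY,
    SynthInterview,
    SynthSpec,
    generate_interview,
)
from asrcurate.textnorm import NormalizedText, normalize


def _text_only_interview(n_utterances: int, words_each: int, seed: int) -> SynthInterview:
    """Interview with dummy audio: boundaries and texts drive the mock backend,
    so tests that never touch the waveform can skip audio synthesis."""
    rng = np.random.default_rng(seed)
    texts = tuple(
        NormalizedText(tuple(rng.choice(DEFAULT_VOCABULARY, size=words_each)))
        for _ in range(n_utterances)
    )
    bounds = tuple(TimeSpan(float(i), float(i) + 0.9) for i in range(n_utterances))
    transcript = NormalizedText(tuple(t for u in texts for t in u.tokens))
    dummy = AudioSignal(16_000, np.zeros(16))
    return SynthInterview(
        audio=dummy, transcript=transcript, true_boundaries=bounds, true_utterance_texts=texts
    )


def _validation_from(interview: SynthInterview, source_id: str):
    return [
        (SegmentAudio(source_id, b, interview.audio), t)
        for b, t in zip(interview.true_boundaries, interview.true_utterance_texts)
    ]


def _is_contiguous_slice(sub: tuple, full: tuple) -> bool:
    if not sub:
        return True
    for i in range(len(full) - len(sub) + 1):
        if full[i:i + len(sub)] == sub:
            return True
    return False


class TestCuratePass:
    def test_perfect_backend_accepts_everything(self, small_interview):
        backend = OracleBackend({"iv": small_interview})
        segs = curate_pass(backend, small_interview.audio, small_interview.transcript, source_id="iv")
        assert segs and all(s.status is SegmentStatus.ACCEPTED for s in segs)
        for s in segs:
            assert s.similarity == 1.0
            assert s.correction.tokens == backend.true_text(
                SegmentAudio("iv", s.span, small_interview.audio)
            ).tokens

    def test_corrupting_backend_partial_acceptance(self):
        iv = generate_interview(
            SynthSpec(n_utterances=20, utterance_duration_s=(1.5, 2.5),
                      silence_duration_ms=(300.0, 500.0), words_per_utterance=(4, 6), seed=77)
        )
        backend = MockBackend({"iv": iv}, word_error_rate=0.3, seed=5)
        segs = curate_pass(backend, iv.audio, iv.transcript, source_id="iv")
        small_interview = iv
        n_acc = sum(s.status is SegmentStatus.ACCEPTED for s in segs)
        assert 0 < n_acc < len(segs)
        for s in segs:
            if s.status is SegmentStatus.ACCEPTED:
                assert s.similarity >= 0.90
                assert _is_contiguous_slice(s.correction.tokens, small_interview.transcript.tokens)
            else:
                assert s.correction is None

    def test_empty_transcript_yields_nothing(self, small_interview):
        backend = OracleBackend({"iv": small_interview})
        assert curate_pass(backend, small_interview.audio, NormalizedText(()), source_id="iv") == []

    def test_backend_failure_marks_segment_error(self, small_interview):
        class FailingBackend(OracleBackend):
            def transcribe(self, segment):
                raise RuntimeError("backend crashed")

        backend = FailingBackend({"iv": small_interview})
        segs = curate_pass(backend, small_interview.audio, small_interview.transcript, source_id="iv")
        assert segs and all(s.status is SegmentStatus.ERROR for s in segs)


class TestMockBackend:
    def test_zero_rate_is_perfect(self):
        iv = _text_only_interview(5, 10, seed=2)
        backend = make_mock_backend({"iv": iv}, word_error_rate=0.0)
        for b, t in zip(iv.true_boundaries, iv.true_utterance_texts):
            assert normalize(backend.transcribe(SegmentAudio("iv", b, iv.audio))).tokens == t.tokens

    def test_transcribe_deterministic_for_fixed_state(self):
        iv = _text_only_interview(3, 10, seed=3)
        backend = make_mock_backend({"iv": iv}, word_error_rate=0.4, seed=8)
        seg = SegmentAudio("iv", iv.true_boundaries[0], iv.audio)
        assert backend.transcribe(seg) == backend.transcribe(seg)

    def test_rate_recovered_before_and_after_finetune(self):
        """Measured WER of the mock's output vs truth on 10,000 words is ~30%
        with rate 0.3, and ~15% after one finetune at improvement factor 0.5."""
        iv = _text_only_interview(1000, 10, seed=4)
        backend = make_mock_backend({"iv": iv}, word_error_rate=0.3, improvement_factor=0.5, seed=21)

        def measured():
            pairs = []
            for b, t in zip(iv.true_boundaries, iv.true_utterance_texts):
                hyp = normalize(backend.transcribe(SegmentAudio("iv", b, iv.audio)))
                pairs.append((t, hyp))
            return corpus_wer(pairs)

        assert measured() == pytest.approx(30.0, abs=2.0)
        backend.finetune([])
        assert measured() == pytest.approx(15.0, abs=2.0)

    def test_invalid_rates_rejected(self):
        iv = _text_only_interview(1, 5, seed=5)
        with pytest.raises(ValueError):
            make_mock_backend({"iv": iv}, word_error_rate=1.5)
        with pytest.raises(ValueError):
            make_mock_backend({"iv": iv}, word_error_rate=0.3, improvement_factor=0.0)


@pytest.fixture(scope="module")
def loop_fixture():
    """Two training interviews plus a disjoint validation interview."""
    train = [
        generate_interview(
            SynthSpec(n_utterances=8, utterance_duration_s=(1.5, 3.0),
                      silence_duration_ms=(300.0, 600.0), words_per_utterance=(6, 10), seed=s)
        )
        for s in (51, 52)
    ]
    val = _text_only_interview(30, 9, seed=53)
    interviews = {f"train{i}": iv for i, iv in enumerate(train)}
    interviews["val"] = val
    corpus = [(iv.audio, iv.transcript, f"train{i}") for i, iv in enumerate(train)]
    validation = _validation_from(val, "val")
    return interviews, corpus, validation


class TestIterate:
    def test_frozen_backend_stops_after_one_iteration(self, loop_fixture):
        interviews, corpus, validation = loop_fixture
        backend = MockBackend(interviews, word_error_rate=0.2, seed=31, frozen=True)
        records = iterate(backend, corpus, validation, IterateConfig())
        assert [r.iteration_index for r in records] == [0, 1]
        assert records[0].validation_wer_pct == records[1].validation_wer_pct
        assert records[1].stop_reason == "plateau"

    def test_improving_backend_matches_iteration_table_shape(self, loop_fixture):
        """Validation WER strictly decreases for at least 3 iterations while
        cumulative accepted samples never shrink, then the loop stops."""
        interviews, corpus, validation = loop_fixture
        backend = MockBackend(interviews, word_error_rate=0.3, improvement_factor=0.5, seed=31)
        records = iterate(backend, corpus, validation, IterateConfig())
        wers = [r.validation_wer_pct for r in records]
        assert len(records) >= 4
        assert all(a > b for a, b in zip(wers[:3], wers[1:4]))
        counts = [r.cumulative_accepted_samples for r in records]
        assert counts == sorted(counts)
        assert records[0].cumulative_accepted_samples == 0
        assert records[-1].stop_reason in ("plateau", "max-iterations", "no-accepted-samples")

    def test_max_iterations_cap(self, loop_fixture):
        interviews, corpus, validation = loop_fixture
        backend = MockBackend(interviews, word_error_rate=0.3, improvement_factor=0.5, seed=31)
        records = iterate(backend, corpus, validation, IterateConfig(max_iterations=2))
        assert [r.iteration_index for r in records] == [0, 1, 2]
        assert records[-1].stop_reason == "max-iterations"

    def test_reproducible_across_runs(self, loop_fixture):
        interviews, corpus, validation = loop_fixture

        def run():
            backend = MockBackend(interviews, word_error_rate=0.3, improvement_factor=0.5, seed=31)
            return iterate(backend, corpus, validation, IterateConfig(max_iterations=4))

        assert run() == run()

    def test_empty_validation_rejected(self, loop_fixture):
        interviews, corpus, _ = loop_fixture
        backend = MockBackend(interviews, word_error_rate=0.3, seed=31)
        with pytest.raises(ValueError):
            iterate(backend, corpus, [], IterateConfig())


def test_iteration_record_invariant_types():
    r = IterationRecord(0, 0, 22.9)
    assert r.stop_reason is None
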
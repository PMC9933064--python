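import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from asrcurate.synthdata import SynthSpec, generate_interview


@pytest.fixture(scope="session")
def small_interview():
    """Six short utterances separated by >=300 ms silences (~25 s of audio)."""
    spec = SynthSpec(
        n_utterances=6,
        utterance_duration_s=(1.5, 3.0),
        silence_duration_ms=(300.0, 600.0),
        words_per_utterance=(4, 8),
        seed=1234,
    )
    return generate_interview(spec)


@pytest.fixture(scope="session")
def tone_interview():
    """Tone-burst variant used where band noise energy would be too variable."""
    spec = SynthSpec(
        n_utterances=4,
        utterance_duration_s=(1.5, 2.5),
        silence_duration_ms=(400.0, 400.0),
        speech_model="tone_burst",
        words_per_utterance=(4, 8),
        seed=99,
    )
    return generate_interview(spec)
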
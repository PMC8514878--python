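import numpy as np
import pytest

from depspeech.audio_io import AudioSignal
from depspeech.synthetic_corpus import CorpusSpec, generate_corpus


def make_tone(freq_hz: float, duration_s: float, rate: int = 16_000,
              amplitude: float = 0.5) -> AudioSignal:
    t = np.arange(int(round(duration_s * rate))) / rate
    return AudioSignal(amplitude * np.sin(2 * np.pi * freq_hz * t), rate)


@pytest.fixture(scope="session")
def tiny_corpus(tmp_path_factory):
    """A 2x2-utterance synthetic corpus on disk (seeded, ~3.5 s each)."""
    out = tmp_path_factory.mktemp("tiny_corpus")
    spec = CorpusSpec(n_per_class=2, duration_s=3.5, seed=11)
    wavs, records, manifest = generate_corpus(spec, out)
    return {"dir": out, "wavs": wavs, "records": records, "manifest": manifest}
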
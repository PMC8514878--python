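import numpy as np
import pytest

from depspeech.phq_labels import load_manifest
from depspeech.preprocess import remove_silence
from depspeech.synthetic_corpus import (ClassAcousticProfile, CorpusSpec,
                                        default_profiles, generate_corpus,
                                        generate_utterance)


class TestGenerateUtterance:
    def test_same_seed_is_bit_identical(self):
        prof = default_profiles()[0]
        a = generate_utterance(prof, 2.0, 16_000, seed=5)
        b = generate_utterance(prof, 2.0, 16_000, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_no_pauses_means_vad_near_identity(self):
        prof = ClassAcousticProfile(f0_mean=140, f0_sd=0, syllable_rate=3.5,
                                    pause_fraction=0.0, amplitude=0.6,
                                    amplitude_sd=0.0, noise_snr_db=60)
        sig = generate_utterance(prof, 2.0, 16_000, seed=1)
        kept = remove_silence(sig)
        assert len(kept) / len(sig) > 0.9

    def test_spectral_peak_at_fundamental(self):
        # one long syllable at a fixed 110 Hz fundamental
        prof = ClassAcousticProfile(f0_mean=110, f0_sd=1e-9, syllable_rate=0.25,
                                    pause_fraction=0.0, amplitude=0.6,
                                    amplitude_sd=0.0, noise_snr_db=60)
        sig = generate_utterance(prof, 4.0, 16_000, seed=2)
        spectrum = np.abs(np.fft.rfft(sig.samples))
        freqs = np.fft.rfftfreq(len(sig), 1 / 16_000)
        peak = freqs[np.argmax(spectrum)]
        bin_width = 16_000 / len(sig)
        assert abs(peak - 110.0) <= bin_width + 1e-9

    def test_peak_amplitude_bounded(self):
        for label, prof in default_profiles().items():
            sig = generate_utterance(prof, 2.0, 16_000, seed=3)
            assert np.abs(sig.samples).max() <= 1.0

    def test_pause_budget_respected(self):
        prof = default_profiles()[1]  # pause_fraction = 0.35
        sig = generate_utterance(prof, 4.0, 16_000, seed=4)
        # silent budget by construction: voiced samples = n_syll * syll_len
        n_syll = round(prof.syllable_rate * 4.0)
        syll_len = round(4.0 * (1 - prof.pause_fraction) / n_syll * 16_000)
        measured_pause = 1.0 - n_syll * syll_len / len(sig)
        assert abs(measured_pause - prof.pause_fraction) <= 0.05

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            ClassAcousticProfile(f0_mean=-1, f0_sd=1, syllable_rate=3,
                                 pause_fraction=0.1, amplitude=0.5,
                                 amplitude_sd=0.1)
        with pytest.raises(ValueError):
            ClassAcousticProfile(f0_mean=100, f0_sd=1, syllable_rate=3,
                                 pause_fraction=1.0, amplitude=0.5,
                                 amplitude_sd=0.1)


class TestGenerateCorpus:
    def test_bookkeeping(self, tmp_path):
        spec = CorpusSpec(n_per_class=5, duration_s=1.0, seed=0)
        wavs, records, manifest = generate_corpus(spec, tmp_path / "c")
        assert len(wavs) == 10
        labels = [r.label for r in records]
        assert labels.count(0) == 5 and labels.count(1) == 5
        assert manifest.exists()

    def test_manifest_items_consistent_with_labels(self, tmp_path):
        spec = CorpusSpec(n_per_class=4, duration_s=1.0, seed=1)
        _, _, manifest = generate_corpus(spec, tmp_path / "c")
        for rec in load_manifest(manifest):
            if rec.label == 1:
                assert rec.score >= 10
            else:
                assert rec.score < 10
            assert rec.consistent

    def test_same_seed_same_corpus(self, tmp_path):
        spec = CorpusSpec(n_per_class=2, duration_s=1.0, seed=9)
        generate_corpus(spec, tmp_path / "a")
        generate_corpus(spec, tmp_path / "b")
        for name in ("P0000.wav", "P1001.wav", "manifest.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()


@pytest.fixture(scope="module")
def contrast_corpus(tmp_path_factory):
    out = tmp_path_factory.mktemp("contrast")
    spec = CorpusSpec(n_per_class=20, duration_s=4.0, seed=7)
    wavs, records, manifest = generate_corpus(spec, out)
    return out, records


class TestClassSeparability:
    def test_depressed_class_pauses_more(self, contrast_corpus):
        from depspeech.audio_io import read_wav
        out, records = contrast_corpus
        voiced = {0: [], 1: []}
        for rec in records:
            sig = read_wav(out / f"{rec.participant_id}.wav")
            kept = remove_silence(sig)
            voiced[rec.label].append(len(kept) / len(sig))
        pause0 = 1 - np.mean(voiced[0])
        pause1 = 1 - np.mean(voiced[1])
        assert pause1 > pause0
        assert np.mean(voiced[0]) - np.mean(voiced[1]) >= 0.1

    def test_control_class_is_louder(self, contrast_corpus):
        from depspeech.audio_io import read_wav
        out, records = contrast_corpus
        rms = {0: [], 1: []}
        for rec in records:
            sig = read_wav(out / f"{rec.participant_id}.wav")
            rms[rec.label].append(np.sqrt(np.mean(sig.samples ** 2)))
        assert np.mean(rms[0]) > np.mean(rms[1])
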
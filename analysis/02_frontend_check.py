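"""Verify the audio front-end on the waveform-level demo corpus.

Runs the gammatone -> Hilbert -> modulation-filterbank -> 25 Hz chain on
a synthetic amplitude-modulated corpus and reports where the feature
variance concentrates (it should track the planted modulation rates).
Writes per-channel variance profiles to results/frontend_variance.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from avmtf import audio, synthetic as syn
from avmtf.filterbanks import GammatoneBank, ModulationFilterbank

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    RESULTS.mkdir(exist_ok=True)
    bank, mfb = GammatoneBank(), ModulationFilterbank()
    rows = []
    for fc in (1.5, 4.0, 8.0):
        gt = syn.SyntheticGroundTruth(
            sources=[syn.SourceSpec(fc, 0.8)], audio_mixing=np.ones((1, 25)),
            visual_mixing=np.ones((1, 204)), audio_noise_sd=0.0,
            visual_noise_sd=0.5, speaker_jitter=0.0, freq_jitter_sd=0.0, seed=seed)
        corpus = syn.generate_waveform_corpus(gt, 1, 1, 10.0, seed=seed)
        w = audio.AudioWaveform(corpus.waveforms[0], corpus.audio_rate)
        X = audio.modulation_decompose(audio.gammatone_envelopes(w, bank), mfb)
        var = X[50:].var(axis=0)
        peak = mfb.center_freqs[var.argmax()]
        print(f"planted {fc:4.1f} Hz -> peak feature variance at {peak:4.1f} Hz "
              f"({'ok' if abs(peak - fc) <= 0.5 else 'MISMATCH'})")
        for f, v in zip(mfb.center_freqs, var):
            rows.append({"planted_hz": fc, "channel_hz": f, "variance": v})
    pd.DataFrame(rows).to_csv(RESULTS / "frontend_variance.csv", index=False)
    print(f"\nvariance profiles -> {RESULTS / 'frontend_variance.csv'}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
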
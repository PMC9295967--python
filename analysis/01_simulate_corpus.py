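"""Generate the synthetic audiovisual corpora used by the analyses.

Writes a small waveform-level corpus (WAV + landmark tables + manifest)
to scratch/corpus_demo/ to document the on-disk corpus format, and
prints the feature-level flagship corpus dimensions used by the later
stages (those corpora are regenerated in memory by each analysis from
the same seeds, so nothing large needs to live on disk).
"""

import sys
from pathlib import Path

import numpy as np

from avmtf import synthetic as syn

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    RESULTS.mkdir(exist_ok=True)
    gt = syn.flagship_ground_truth(seed=seed)
    print("Flagship study conditions")
    for s in gt.sources:
        print(f"  source: {s.center_freq} Hz (bw {s.bandwidth} Hz, amp {s.amplitude})")
    print(f"  noise SDs: audio {gt.audio_noise_sd}, visual {gt.visual_noise_sd}")
    print(f"  speaker jitter: {gt.speaker_jitter} (mixing), {gt.freq_jitter_sd} Hz (rate)")

    corpus = syn.generate_feature_corpus(gt, 30, 5, 1500, seed=seed)
    print(f"\nFeature-level flagship corpus: {len(corpus.video_ids)} videos, "
          f"{len(corpus.speakers())} speakers, {corpus.X_A[0].shape[0]} frames/video "
          f"({corpus.X_A[0].shape[0] / 25:.0f} s at 25 fps)")

    demo = syn.generate_waveform_corpus(gt, 2, 2, 4.0, seed=seed)
    scratch = Path(__file__).resolve().parent.parent / "scratch"
    out = syn.write_waveform_corpus(demo, scratch / "corpus_demo")
    print(f"\nWaveform-level demo corpus written to {out}")
    print(f"  mean rectified-modulator fraction: {np.mean(demo.clip_fractions):.4f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
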
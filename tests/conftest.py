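import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from ecgpipe.imaging import RenderSettings, build_image_dataset

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")
from ecgpipe.segmentation import RPeakList, segment_beats
from ecgpipe.synthetic import BeatClass, generate_recording


def collect_beats(n_per_class: int, seed: int = 42, duration_s: float = 60.0,
                  rr_jitter: float = 0.03, amp_jitter: float = 0.02):
    """Segment ground-truth-anchored beats of every class from synthetic
    recordings at varied heart rates, n per class."""
    rng = np.random.default_rng(seed)
    beats = []
    for cls in BeatClass:
        got = 0
        while got < n_per_class:
            rec = generate_recording(
                cls, duration_s=duration_s, fs=360.0,
                heart_rate_bpm=float(rng.uniform(60, 100)),
                seed=int(rng.integers(2 ** 31)),
                rr_jitter_frac=rr_jitter, amplitude_jitter_frac=amp_jitter)
            segs = segment_beats(rec.signal,
                                 RPeakList(rec.true_r_peaks, rec.signal.fs),
                                 list(rec.beat_labels))
            take = segs[: n_per_class - got]
            beats.extend(take)
            got += len(take)
    return beats


@pytest.fixture(scope="session")
def small_image_dataset(tmp_path_factory):
    """4 x 24 labelled beat images (128 px) with their manifest, on disk."""
    root = tmp_path_factory.mktemp("images")
    beats = collect_beats(24, seed=7)
    manifest = build_image_dataset(beats, root, settings=RenderSettings(size=128))
    return root, manifest
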
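"""End-to-end helpers: soundscape -> front end -> recognizer -> durations.

Convenience plumbing for running the full monitoring chain over sequences
of one-minute soundscapes, mirroring how recordings are processed in
60-second segments.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calls import SoundscapeConfig, synth_soundscape
from .frontend import AudioSegment, FrontendConfig, preprocess
from .quantify import threshold_durations
from .recognizer import VocalizationNet, infer

__all__ = ["estimate_minute_durations", "run_synthetic_minutes"]


def estimate_minute_durations(
    model: VocalizationNet,
    segments: Iterable[tuple[np.ndarray, int, float]],
    frontend_config: FrontendConfig | None = None,
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Process (waveform, sample_rate, start_clock_s) segments through the
    full chain and concatenate the per-minute duration tables."""
    fc = frontend_config or FrontendConfig()
    parts = []
    for wave, sr, start in segments:
        spec = preprocess(AudioSegment(wave, sr, start_clock=start), fc)
        raster = infer(model, spec)
        parts.append(threshold_durations(raster, threshold))
    out = pd.concat(parts)
    return out.groupby(level=0).sum()


def run_synthetic_minutes(
    model: VocalizationNet,
    configs: Sequence[SoundscapeConfig],
    frontend_config: FrontendConfig | None = None,
    threshold: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize one-minute soundscapes, run the chain, and return
    (estimated, ground-truth) per-minute duration tables aligned by minute."""
    est_parts, truth_parts = [], []
    fc = frontend_config or FrontendConfig()
    for i, cfg in enumerate(configs):
        wave, truth = synth_soundscape(cfg)
        spec = preprocess(AudioSegment(wave, cfg.sample_rate, start_clock=60.0 * i), fc)
        raster = infer(model, spec)
        est = threshold_durations(raster, threshold)
        est.index = pd.RangeIndex(i, i + len(est), name="minute")
        est_parts.append(est)
        td = truth.minute_durations
        td.index = pd.RangeIndex(i, i + len(td), name="minute")
        truth_parts.append(td)
    est = pd.concat(est_parts).groupby(level=0).sum()
    tru = pd.concat(truth_parts).groupby(level=0).sum()
    return est.reindex(tru.index, fill_value=0.0), tru
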
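"""Windowed-means ERP feature extraction.

The pipeline follows the standard windowed-means paradigm for P300
detection: per-trial baseline correction against the 500 ms pre-stimulus
interval, averaging each channel inside consecutive 50 ms windows from
150 to 700 ms post-stimulus (11 windows), channel-major concatenation
(19 channels x 11 windows = 209 features), and per-trial normalization
to unit Euclidean length.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from p300sae.io import EpochSet


@dataclass(eq=False)
class FeatureMatrix:
    """Trials x features matrix with class labels.

    ``feature_names`` are ``"channel:start_ms"`` descriptors in
    channel-major concatenation order, so the layout is auditable.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.feature_names and len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must equal feature count")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            np.array_equal(self.values, other.values)
            and np.array_equal(self.labels, other.labels)
            and self.feature_names == other.feature_names
        )

    def to_text(self, path) -> None:
        """Write as delimited text: one row per trial, label column last."""
        header = "\t".join(self.feature_names + ["label"]) if self.feature_names else ""
        body = np.column_stack([self.values, self.labels.astype(float)])
        np.savetxt(path, body, delimiter="\t", header=header, comments="")


def baseline_correct(epochs: EpochSet, baseline_ms: float = 500.0) -> EpochSet:
    """Subtract the mean of the pre-stimulus baseline from each trial.

    The baseline is the ``baseline_ms`` interval immediately preceding
    stimulus onset, per trial and channel.
    """
    fs = epochs.sampling_rate
    n_base = int(round(baseline_ms * fs / 1000.0))
    if n_base < 1 or epochs.t0_offset < n_base:
        raise ValueError(
            f"epoch has {epochs.t0_offset} pre-stimulus samples, "
            f"baseline of {baseline_ms} ms needs {n_base}"
        )
    base = epochs.data[:, :, epochs.t0_offset - n_base : epochs.t0_offset].mean(axis=2, keepdims=True)
    return dataclasses.replace(epochs, data=epochs.data - base)


def windowed_means(
    epochs: EpochSet,
    start_ms: float = 150.0,
    end_ms: float = 700.0,
    width_ms: float = 50.0,
) -> FeatureMatrix:
    """Average each channel in consecutive post-stimulus time windows.

    Windows are half-open ``[w, w + width)`` in milliseconds post
    stimulus, mapped to sample indices by ``floor(t * fs / 1000)``; at
    1 kHz each default window holds exactly 50 samples.  Features are
    concatenated channel-major (all windows of channel 1, then channel
    2, ...), giving ``n_channels * n_windows`` columns.
    """
    if width_ms <= 0 or end_ms <= start_ms:
        raise ValueError("need end_ms > start_ms and width_ms > 0")
    n_windows = (end_ms - start_ms) / width_ms
    if abs(n_windows - round(n_windows)) > 1e-9:
        raise ValueError(f"(end - start) = {end_ms - start_ms} ms not divisible by width {width_ms} ms")
    n_windows = int(round(n_windows))
    fs = epochs.sampling_rate
    n_trials, n_channels, n_samples = epochs.data.shape

    edges_ms = start_ms + width_ms * np.arange(n_windows + 1)
    edges = epochs.t0_offset + np.floor(edges_ms * fs / 1000.0).astype(int)
    if edges[-1] > n_samples:
        raise ValueError(
            f"window ending at {end_ms} ms post-stimulus exceeds the epoch "
            f"({(n_samples - epochs.t0_offset) * 1000.0 / fs:.0f} ms available)"
        )

    feats = np.empty((n_trials, n_channels, n_windows))
    for w in range(n_windows):
        feats[:, :, w] = epochs.data[:, :, edges[w] : edges[w + 1]].mean(axis=2)
    values = feats.reshape(n_trials, n_channels * n_windows)

    ch_names = epochs.channel_labels or [f"ch{c:02d}" for c in range(n_channels)]
    names = [f"{ch}:{int(edges_ms[w])}ms" for ch in ch_names for w in range(n_windows)]
    return FeatureMatrix(values=values, labels=epochs.labels.copy(), feature_names=names)


def normalize_rows(matrix: FeatureMatrix) -> FeatureMatrix:
    """Divide each feature vector by its Euclidean length."""
    norms = np.linalg.norm(matrix.values, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"cannot normalize all-zero feature vector(s) at trial index {zero.tolist()}")
    return dataclasses.replace(matrix, values=matrix.values / norms[:, None])


def extract_features(
    epochs: EpochSet,
    start_ms: float = 150.0,
    end_ms: float = 700.0,
    width_ms: float = 50.0,
    baseline_ms: float = 500.0,
) -> FeatureMatrix:
    """Baseline-correct, window-average and length-normalize in one call."""
    return normalize_rows(windowed_means(baseline_correct(epochs, baseline_ms), start_ms, end_ms, width_ms))
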
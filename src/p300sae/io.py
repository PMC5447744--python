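"""Recording containers, BrainVision I/O, epoching and trial-set assembly.

The central in-memory objects are :class:`ContinuousRecording` (a
multi-channel signal plus an ordered stimulus-marker track) and
:class:`EpochSet` (marker-locked trials with class labels).  Recordings
can be read from BrainVision ``.vhdr/.vmrk/.eeg`` triplets (via MNE) or
from the package's own HDF5 container, which round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import h5py
import numpy as np

logger = logging.getLogger(__name__)

#: Default marker strings, matching common BrainVision stimulus codes for
#: target (green) and non-target (red) flashes.
TARGET_CODE = "S  2"
NONTARGET_CODE = "S  4"
DISTRACTOR_CODE = "S  8"


class FormatError(Exception):
    """A file could not be parsed as the expected format."""


def _normalize_code(code: str) -> str:
    """Collapse runs of whitespace; BrainVision writers pad marker codes
    differently ("S 2" vs "S  2")."""
    return " ".join(code.split())


@dataclass(eq=False)
class ContinuousRecording:
    """Multi-channel sampled signal (microvolts) with stimulus markers.

    Parameters
    ----------
    signal
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    sampling_rate
        Sampling frequency in Hz.
    channel_labels
        One name per channel, in signal row order.
    markers
        Ordered ``(onset_sample, code)`` pairs; onsets in samples.
    metadata
        Free-form dictionary (subject id, phase boundaries, ...).
    """

    signal: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    markers: list[tuple[int, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1 or self.signal.shape[1] < 1:
            raise ValueError("signal must be a (n_channels, n_samples) array with at least one of each")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"channel_labels has {len(self.channel_labels)} entries for {self.signal.shape[0]} channels"
            )
        n = self.signal.shape[1]
        self.markers = [(int(onset), str(code)) for onset, code in self.markers]
        for onset, _ in self.markers:
            if not 0 <= onset < n:
                raise ValueError(f"marker onset {onset} outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContinuousRecording):
            return NotImplemented
        return (
            np.array_equal(self.signal, other.signal)
            and self.sampling_rate == other.sampling_rate
            and self.channel_labels == other.channel_labels
            and self.markers == other.markers
            and self.metadata == other.metadata
        )


@dataclass(eq=False)
class EpochSet:
    """Marker-locked trials: ``data`` is ``(n_trials, n_channels, n_samples)``.

    ``labels`` holds 1 for target trials and 0 for non-target trials.
    ``t0_offset`` is the number of samples from epoch start to stimulus
    onset (500 at 1 kHz with the standard -500..+1000 ms window).
    """

    data: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    t0_offset: int
    subject_id: str | None = None
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if not 0 <= self.t0_offset <= self.data.shape[2]:
            raise ValueError("t0_offset outside epoch span")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and self.sampling_rate == other.sampling_rate
            and self.t0_offset == other.t0_offset
            and self.subject_id == other.subject_id
        )


# ---------------------------------------------------------------------------
# Internal HDF5 container
# ---------------------------------------------------------------------------

def write_container(recording: ContinuousRecording, path: str | os.PathLike) -> None:
    """Write a recording to the single-file HDF5 container (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=recording.signal)
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["channel_labels"] = [str(c) for c in recording.channel_labels]
        g = f.create_group("markers")
        g.create_dataset("onsets", data=np.array([m[0] for m in recording.markers], dtype=np.int64))
        g.create_dataset(
            "codes",
            data=np.array([m[1] for m in recording.markers], dtype=object),
            dtype=h5py.string_dtype(),
        )
        f.attrs["metadata"] = json.dumps(recording.metadata)


def read_container(path: str | os.PathLike) -> ContinuousRecording:
    """Read a recording written by :func:`write_container`.

    Raises
    ------
    FormatError
        If the file is missing, truncated or lacks required fields.
    """
    try:
        with h5py.File(path, "r") as f:
            signal = f["signal"][()]
            fs = float(f.attrs["sampling_rate"])
            labels = [c if isinstance(c, str) else c.decode() for c in f.attrs["channel_labels"]]
            onsets = f["markers/onsets"][()]
            codes = [c if isinstance(c, str) else c.decode() for c in f["markers/codes"][()]]
            metadata = json.loads(f.attrs["metadata"])
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read container {path}: {exc}") from exc
    markers = [(int(o), c) for o, c in zip(onsets, codes)]
    return ContinuousRecording(signal, fs, labels, markers, metadata)


def save_epochs(epochs: EpochSet, path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["t0_offset"] = epochs.t0_offset
        f.attrs["subject_id"] = epochs.subject_id or ""
        f.attrs["channel_labels"] = [str(c) for c in (epochs.channel_labels or [])]


def load_epochs(path: str | os.PathLike) -> EpochSet:
    try:
        with h5py.File(path, "r") as f:
            labels = [c if isinstance(c, str) else c.decode() for c in f.attrs["channel_labels"]]
            return EpochSet(
                data=f["data"][()],
                labels=f["labels"][()],
                sampling_rate=float(f.attrs["sampling_rate"]),
                t0_offset=int(f.attrs["t0_offset"]),
                subject_id=str(f.attrs["subject_id"]) or None,
                channel_labels=labels or None,
            )
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read epoch container {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# BrainVision triplets
# ---------------------------------------------------------------------------

def read_brainvision(header_path: str | os.PathLike) -> ContinuousRecording:
    """Read a BrainVision ``.vhdr`` triplet into a recording in microvolts.

    Stimulus marker codes are reported verbatim (e.g. ``"S  2"``), with
    MNE's ``"Stimulus/"`` annotation prefix stripped.
    """
    import mne

    header_path = os.fspath(header_path)
    if not os.path.exists(header_path):
        raise FormatError(f"header file not found: {header_path}")
    try:
        raw = mne.io.read_raw_brainvision(header_path, preload=True, verbose="error")
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read BrainVision triplet {header_path}: {exc}") from exc
    signal = raw.get_data() * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    markers: list[tuple[int, str]] = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("New Segment"):
            continue
        for prefix in ("Stimulus/", "Response/", "Comment/"):
            if desc.startswith(prefix):
                desc = desc[len(prefix):]
                break
        markers.append((int(round(ann["onset"] * fs)), desc))
    return ContinuousRecording(
        signal,
        fs,
        list(raw.ch_names),
        markers,
        {"source": header_path},
    )


def write_brainvision(
    recording: ContinuousRecording,
    header_path: str | os.PathLike,
    resolution: float = 0.1,
) -> None:
    """Write a minimal BrainVision triplet (INT_16 multiplexed dialect).

    ``resolution`` is the microvolt value of one integer step (0.1 uV by
    default, the amplifier setting the package's pipeline assumes).
    Intended for fixtures and interoperability tests, not archival.
    """
    header_path = os.fspath(header_path)
    if not header_path.endswith(".vhdr"):
        raise ValueError("header path must end in .vhdr")
    base = os.path.basename(header_path)[:-5]
    directory = os.path.dirname(header_path) or "."
    eeg_name, vmrk_name = base + ".eeg", base + ".vmrk"

    data_int = np.round(recording.signal / resolution)
    if np.any(np.abs(data_int) > 32767):
        raise ValueError("signal exceeds INT_16 range at this resolution")
    # multiplexed: sample-major interleaving, little-endian int16
    with open(os.path.join(directory, eeg_name), "wb") as f:
        f.write(data_int.T.astype("<i2").tobytes())

    sampling_interval_us = 1e6 / recording.sampling_rate
    si = f"{sampling_interval_us:.6f}".rstrip("0").rstrip(".")
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={recording.n_channels}",
        f"SamplingInterval={si}",
        "",
        "[Binary Infos]",
        "BinaryFormat=INT_16",
        "",
        "[Channel Infos]",
    ]
    res = f"{resolution:g}"
    for i, name in enumerate(recording.channel_labels, start=1):
        lines.append(f"Ch{i}={name},,{res},µV")
    with open(header_path, "w", encoding="utf-8") as f:
        f.write("\n".join(lines) + "\n")

    mlines = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg_name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for k, (onset, code) in enumerate(recording.markers, start=2):
        # BrainVision marker positions are 1-based data points
        mlines.append(f"Mk{k}=Stimulus,{code},{onset + 1},1,0")
    with open(os.path.join(directory, vmrk_name), "w", encoding="utf-8") as f:
        f.write("\n".join(mlines) + "\n")


# ---------------------------------------------------------------------------
# Epoching and trial-set assembly
# ---------------------------------------------------------------------------

def extract_epochs(
    recording: ContinuousRecording,
    target_code: str = TARGET_CODE,
    nontarget_code: str = NONTARGET_CODE,
    pre_ms: float = 500.0,
    post_ms: float = 1000.0,
) -> EpochSet:
    """Cut marker-locked trials around target / non-target markers.

    Each trial spans the half-open window ``[onset - pre, onset + post)``
    in samples; at 1 kHz with the default window this is exactly 1500
    samples with stimulus onset at sample 500.  Markers with other codes
    (e.g. distractors) are ignored; trials that would overrun either edge
    of the recording are dropped and counted in the log.
    """
    if pre_ms <= 0 or post_ms <= 0:
        raise ValueError("pre_ms and post_ms must be positive")
    fs = recording.sampling_rate
    pre = int(round(pre_ms * fs / 1000.0))
    post = int(round(post_ms * fs / 1000.0))
    tgt = _normalize_code(target_code)
    ntg = _normalize_code(nontarget_code)

    trials, labels = [], []
    n_dropped = 0
    for onset, code in recording.markers:
        norm = _normalize_code(code)
        if norm == tgt:
            label = 1
        elif norm == ntg:
            label = 0
        else:
            continue
        lo, hi = onset - pre, onset + post
        if lo < 0 or hi > recording.n_samples:
            n_dropped += 1
            continue
        trials.append(recording.signal[:, lo:hi])
        labels.append(label)
    if n_dropped:
        logger.info("extract_epochs: dropped %d edge-overrunning trials", n_dropped)
    if not trials:
        logger.warning("extract_epochs: no markers matched codes %r / %r", target_code, nontarget_code)
        data = np.empty((0, recording.n_channels, pre + post))
    else:
        data = np.stack(trials)
    return EpochSet(
        data=data,
        labels=np.array(labels, dtype=np.int8),
        sampling_rate=fs,
        t0_offset=pre,
        subject_id=recording.metadata.get("subject_id"),
        channel_labels=list(recording.channel_labels),
    )


def assemble_training_set(epoch_sets: list[EpochSet], rng: np.random.Generator | int) -> EpochSet:
    """Merge subjects into one balanced, shuffled training set.

    From each subject all target trials are kept and an equally sized
    uniform random subset of its non-target trials is drawn; the union
    over subjects is then randomly shuffled.
    """
    if not epoch_sets:
        raise ValueError("need at least one subject epoch set")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    parts_data, parts_labels = [], []
    for es in epoch_sets:
        t_idx = np.flatnonzero(es.labels == 1)
        n_idx = np.flatnonzero(es.labels == 0)
        if len(n_idx) < len(t_idx):
            raise ValueError(
                f"subject {es.subject_id}: {len(n_idx)} non-targets < {len(t_idx)} targets"
            )
        chosen = rng.choice(n_idx, size=len(t_idx), replace=False)
        keep = np.concatenate([t_idx, chosen])
        parts_data.append(es.data[keep])
        parts_labels.append(es.labels[keep])
    data = np.concatenate(parts_data)
    labels = np.concatenate(parts_labels)
    order = rng.permutation(len(labels))
    ref = epoch_sets[0]
    return EpochSet(
        data=data[order],
        labels=labels[order],
        sampling_rate=ref.sampling_rate,
        t0_offset=ref.t0_offset,
        subject_id="merged",
        channel_labels=ref.channel_labels,
    )


def select_test_trials(epoch_set: EpochSet) -> EpochSet:
    """Balanced per-subject test set: all targets plus the first
    (chronological) equal number of non-target trials."""
    t_idx = np.flatnonzero(epoch_set.labels == 1)
    n_idx = np.flatnonzero(epoch_set.labels == 0)
    if len(n_idx) < len(t_idx):
        raise ValueError(
            f"subject {epoch_set.subject_id}: {len(n_idx)} non-targets < {len(t_idx)} targets"
        )
    keep = np.sort(np.concatenate([t_idx, n_idx[: len(t_idx)]]))
    return EpochSet(
        data=epoch_set.data[keep],
        labels=epoch_set.labels[keep],
        sampling_rate=epoch_set.sampling_rate,
        t0_offset=epoch_set.t0_offset,
        subject_id=epoch_set.subject_id,
        channel_labels=epoch_set.channel_labels,
    )


def split_validation(matrix, fraction: float = 0.2, rng: np.random.Generator | int = 0):
    """Random disjoint train/validation split of a feature matrix.

    The validation size is ``round(n * fraction)``.  Row order within each
    part follows the original matrix.  Works on any dataclass with
    ``values`` and ``labels`` fields (i.e. :class:`~p300sae.features.FeatureMatrix`).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = len(matrix.labels)
    n_val = int(round(n * fraction))
    if n_val == 0 or n_val == n:
        raise ValueError(f"degenerate split: {n} rows at fraction {fraction}")
    perm = rng.permutation(n)
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])
    train = dataclasses.replace(matrix, values=matrix.values[train_idx], labels=matrix.labels[train_idx])
    val = dataclasses.replace(matrix, values=matrix.values[val_idx], labels=matrix.labels[val_idx])
    return train, val
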
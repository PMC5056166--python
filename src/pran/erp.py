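"""Epoch-level EEG reduction to windowed ROI mean amplitudes.

Epochs are time-locked to F0 (pitch) onset and reduced in four steps:
baseline correction over a pre-stimulus interval, +/-threshold artifact
rejection, averaging across epochs sharing a word-initial fragment (within
subject, then unweighted across subjects), and averaging over region-of-
interest channels within an analysis time window.  Window and baseline
endpoints are inclusive on both sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicon import WIFKey

__all__ = [
    "ROISpec",
    "MONTAGES",
    "MONTAGE_EXP1_3",
    "MONTAGE_EXP2",
    "montage_channels",
    "EpochSet",
    "ItemERPs",
    "SubjectERPs",
    "load_epochs",
    "write_epochs",
    "baseline_correct",
    "reject_artifacts",
    "item_erps",
    "subject_wif_erps",
    "window_roi_amplitudes",
]


@dataclass(frozen=True)
class ROISpec:
    """A named electrode group with its topographic factor levels."""

    name: str
    channels: tuple[str, ...]
    antpost: str
    laterality: str


# Experiments 1 and 3: 6 ROIs of 2 channels each.
MONTAGE_EXP1_3: tuple[ROISpec, ...] = (
    ROISpec("left anterior", ("F7", "F3"), "anterior", "left"),
    ROISpec("right anterior", ("F4", "F8"), "anterior", "right"),
    ROISpec("left central", ("T7", "C3"), "central", "left"),
    ROISpec("right central", ("C4", "T8"), "central", "right"),
    ROISpec("left posterior", ("P7", "P3"), "posterior", "left"),
    ROISpec("right posterior", ("P4", "P8"), "posterior", "right"),
)

# Experiment 2: 9 ROIs of 6 channels each (3x3 Antpost x Laterality grid).
MONTAGE_EXP2: tuple[ROISpec, ...] = (
    ROISpec("left anterior", ("F7", "F5", "F3", "FT7", "FC5", "FC3"), "anterior", "left"),
    ROISpec("mid anterior", ("F1", "FZ", "F2", "FC1", "FCZ", "FC2"), "anterior", "mid"),
    ROISpec("right anterior", ("F4", "F6", "F8", "FC4", "FC6", "FT8"), "anterior", "right"),
    ROISpec("left central", ("T7", "C5", "C3", "TP7", "CP5", "CP3"), "central", "left"),
    ROISpec("mid central", ("C1", "CZ", "C2", "CP1", "CPZ", "CP2"), "central", "mid"),
    ROISpec("right central", ("C4", "C6", "T8", "CP4", "CP6", "TP8"), "central", "right"),
    ROISpec("left posterior", ("P7", "P5", "P3", "PO7", "PO5", "O1"), "posterior", "left"),
    ROISpec("mid posterior", ("P1", "PZ", "P2", "PO3", "PO4", "OZ"), "posterior", "mid"),
    ROISpec("right posterior", ("P4", "P6", "P8", "PO6", "PO8", "O2"), "posterior", "right"),
)

MONTAGES: Mapping[str, tuple[ROISpec, ...]] = {
    "exp1_3": MONTAGE_EXP1_3,
    "exp2": MONTAGE_EXP2,
}


def montage_channels(montage: Sequence[ROISpec]) -> list[str]:
    out: list[str] = []
    for roi in montage:
        out.extend(roi.channels)
    return out


@dataclass
class EpochSet:
    """Dense subject x item x channel x sample amplitude array in microvolts.

    ``sample_times`` are milliseconds relative to F0 onset on a uniform grid.
    ``rejected`` marks (subject, item) epochs excluded from every average.
    """

    amplitudes: np.ndarray
    sample_times: np.ndarray
    channel_labels: list[str]
    subjects: list[str]
    items: list[str]
    item_wif: dict[str, WIFKey]
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if self.amplitudes.ndim != 4:
            raise ValueError("amplitudes must be 4-dimensional")
        n_s, n_i, n_c, n_t = self.amplitudes.shape
        if (len(self.subjects), len(self.items), len(self.channel_labels)) != (n_s, n_i, n_c):
            raise ValueError("label lists do not match amplitude shape")
        if len(self.sample_times) != n_t:
            raise ValueError("sample_times does not match amplitude shape")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.rejected is None:
            self.rejected = np.zeros((n_s, n_i), dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
            if self.rejected.shape != (n_s, n_i):
                raise ValueError("rejected mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.amplitudes.shape


@dataclass
class ItemERPs:
    """Grand-average waveform per WIF: (n_wif, n_channel, n_sample)."""

    wifs: list[WIFKey]
    waveforms: np.ndarray
    channel_labels: list[str]
    sample_times: np.ndarray


@dataclass
class SubjectERPs:
    """Subject-resolved WIF averages: (n_subject, n_wif, n_channel, n_sample);
    NaN where a subject has no surviving epoch for a WIF."""

    subjects: list[str]
    wifs: list[WIFKey]
    waveforms: np.ndarray
    channel_labels: list[str]
    sample_times: np.ndarray


def write_epochs(
    epochs: EpochSet, path: str | Path, items_path: str | Path | None = None
) -> None:
    """Write long-format TSV (subject, item, channel, time_ms, amplitude_uv)
    plus, optionally, the item -> WIF mapping as a companion TSV."""
    n_s, n_i, n_c, n_t = epochs.shape
    subj = np.repeat(epochs.subjects, n_i * n_c * n_t)
    item = np.tile(np.repeat(epochs.items, n_c * n_t), n_s)
    chan = np.tile(np.repeat(epochs.channel_labels, n_t), n_s * n_i)
    time = np.tile(epochs.sample_times, n_s * n_i * n_c)
    df = pd.DataFrame(
        {
            "subject": subj,
            "item": item,
            "channel": chan,
            "time_ms": time,
            "amplitude_uv": epochs.amplitudes.ravel(),
        }
    )
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if items_path is not None:
        pd.DataFrame(
            {
                "item": epochs.items,
                "wif_segments": [" ".join(epochs.item_wif[i].segments) for i in epochs.items],
                "accent": [epochs.item_wif[i].accent for i in epochs.items],
            }
        ).to_csv(items_path, sep="\t", index=False)


def load_epochs(
    path: str | Path,
    items_path: str | Path | None = None,
    channels: Sequence[str] | None = None,
    item_wif: Mapping[str, WIFKey] | None = None,
) -> EpochSet:
    """Load a long-format epoch table into a dense :class:`EpochSet`.

    Every (subject, item, channel, time) cell must be present exactly once;
    missing cells are an error (no imputation).  ``channels``, when given,
    declares the known montage labels and unknown labels are an error.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"subject": str, "item": str, "channel": str},
        float_precision="round_trip",
    )
    subjects = list(pd.unique(df["subject"]))
    items = list(pd.unique(df["item"]))
    chans = list(pd.unique(df["channel"]))
    if channels is not None:
        unknown = sorted(set(chans) - set(channels))
        if unknown:
            raise ValueError(f"unknown channel label(s): {', '.join(unknown)}")
    times = np.sort(df["time_ms"].unique().astype(float))
    steps = np.diff(times)
    if len(steps) and not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise ValueError("non-uniform time grid")
    shape = (len(subjects), len(items), len(chans), len(times))
    arr = np.full(shape, np.nan)
    s_ix = {s: i for i, s in enumerate(subjects)}
    i_ix = {s: i for i, s in enumerate(items)}
    c_ix = {s: i for i, s in enumerate(chans)}
    t_ix = {t: i for i, t in enumerate(times)}
    arr[
        df["subject"].map(s_ix).to_numpy(),
        df["item"].map(i_ix).to_numpy(),
        df["channel"].map(c_ix).to_numpy(),
        df["time_ms"].astype(float).map(t_ix).to_numpy(),
    ] = df["amplitude_uv"].to_numpy(dtype=float)
    missing = np.argwhere(np.isnan(arr))
    if len(missing):
        s, i, c, t = missing[0]
        raise ValueError(
            "missing cell: subject=%s item=%s channel=%s time_ms=%g"
            % (subjects[s], items[i], chans[c], times[t])
        )
    mapping: dict[str, WIFKey]
    if items_path is not None:
        idf = pd.read_csv(items_path, sep="\t", dtype={"item": str})
        mapping = {
            str(r["item"]): WIFKey(tuple(str(r["wif_segments"]).split()), int(r["accent"]))
            for _, r in idf.iterrows()
        }
    elif item_wif is not None:
        mapping = dict(item_wif)
    else:
        raise ValueError("provide items_path or item_wif to map items to WIFs")
    absent = [i for i in items if i not in mapping]
    if absent:
        raise ValueError(f"items without WIF mapping: {', '.join(absent)}")
    return EpochSet(arr, times, chans, subjects, items, mapping)


def baseline_correct(
    epochs: EpochSet, baseline: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract each trace's mean over the baseline interval (inclusive)."""
    lo, hi = baseline
    if lo >= hi:
        raise ValueError("baseline interval must be ordered (start < end)")
    t = epochs.sample_times
    if lo < t[0] or hi > t[-1]:
        raise ValueError("baseline interval outside the sampled range")
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError("baseline interval contains no samples")
    means = epochs.amplitudes[..., mask].mean(axis=-1, keepdims=True)
    return replace(epochs, amplitudes=epochs.amplitudes - means,
                   rejected=epochs.rejected.copy())


def reject_artifacts(
    epochs: EpochSet, threshold: float = 100.0
) -> tuple[EpochSet, pd.DataFrame]:
    """Mark epochs whose amplitude magnitude exceeds ``threshold`` anywhere.

    Returns the updated set (mask OR-ed onto existing rejections) and a
    per-subject rejection log.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bad = np.abs(epochs.amplitudes) > threshold
    mask = bad.any(axis=(2, 3))
    rejected = epochs.rejected | mask
    log = pd.DataFrame(
        {
            "subject": epochs.subjects,
            "n_rejected": mask.sum(axis=1),
            "n_total": [len(epochs.items)] * len(epochs.subjects),
        }
    )
    return replace(epochs, amplitudes=epochs.amplitudes, rejected=rejected), log


def _wif_order(epochs: EpochSet) -> list[WIFKey]:
    return sorted(set(epochs.item_wif[i] for i in epochs.items))


def subject_wif_erps(epochs: EpochSet) -> SubjectERPs:
    """Stage one of grand averaging: each subject's mean over their
    unrejected epochs of each WIF (items sharing a WIF pooled)."""
    wifs = _wif_order(epochs)
    n_s, _, n_c, n_t = epochs.shape
    out = np.full((n_s, len(wifs), n_c, n_t), np.nan)
    item_idx = {w: [] for w in wifs}
    for j, it in enumerate(epochs.items):
        item_idx[epochs.item_wif[it]].append(j)
    keep = ~epochs.rejected
    for k, wif in enumerate(wifs):
        cols = np.asarray(item_idx[wif])
        sub_keep = keep[:, cols]  # (n_s, n_items_of_wif)
        w = sub_keep[:, :, None, None]
        with np.errstate(invalid="ignore"):
            sums = np.where(w, epochs.amplitudes[:, cols], 0.0).sum(axis=1)
            n = sub_keep.sum(axis=1)[:, None, None]
            out[:, k] = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    return SubjectERPs(list(epochs.subjects), wifs, out,
                       list(epochs.channel_labels), epochs.sample_times)


def item_erps(epochs: EpochSet) -> ItemERPs:
    """Grand-average waveform per WIF: within-subject means first, then an
    unweighted mean across subjects.  WIFs with no surviving epoch anywhere
    are excluded with a warning."""
    subj = subject_wif_erps(epochs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        grand = np.nanmean(subj.waveforms, axis=0)
    dead = np.isnan(grand).all(axis=(1, 2))
    if dead.any():
        names = [subj.wifs[k].label for k in np.flatnonzero(dead)]
        warnings.warn(f"WIF(s) with no surviving epochs excluded: {', '.join(names)}",
                      stacklevel=2)
    keep = np.flatnonzero(~dead)
    return ItemERPs([subj.wifs[k] for k in keep], grand[keep],
                    subj.channel_labels, subj.sample_times)


def window_roi_amplitudes(
    erps: ItemERPs | SubjectERPs,
    rois: Sequence[ROISpec],
    window: tuple[float, float],
) -> pd.DataFrame:
    """Mean amplitude over ROI channels x window samples, per (wif, roi)
    (and per subject for :class:`SubjectERPs` input).

    Window endpoints are inclusive.  Returns a long DataFrame with columns
    wif_segments, accent, roi, amplitude (+ subject when applicable).
    """
    lo, hi = window
    t = erps.sample_times
    if lo < t[0] or hi > t[-1]:
        raise ValueError("analysis window outside the sampled range")
    tmask = (t >= lo) & (t <= hi)
    if not tmask.any():
        raise ValueError("analysis window contains no samples")
    c_ix = {c: i for i, c in enumerate(erps.channel_labels)}
    rows = []
    for roi in rois:
        if not roi.channels:
            raise ValueError(f"ROI {roi.name} has no channels")
        missing = [c for c in roi.channels if c not in c_ix]
        if missing:
            raise ValueError(f"ROI {roi.name} channels not in data: {', '.join(missing)}")
        cols = [c_ix[c] for c in roi.channels]
        if isinstance(erps, SubjectERPs):
            vals = erps.waveforms[:, :, cols][..., tmask].mean(axis=(2, 3))
            for si, subject in enumerate(erps.subjects):
                for wi, wif in enumerate(erps.wifs):
                    rows.append((subject, " ".join(wif.segments), wif.accent,
                                 roi.name, vals[si, wi]))
        else:
            vals = erps.waveforms[:, cols][..., tmask].mean(axis=(1, 2))
            for wi, wif in enumerate(erps.wifs):
                rows.append((" ".join(wif.segments), wif.accent, roi.name, vals[wi]))
    if isinstance(erps, SubjectERPs):
        return pd.DataFrame(rows, columns=["subject", "wif_segments", "accent",
                                           "roi", "amplitude"])
    return pd.DataFrame(rows, columns=["wif_segments", "accent", "roi", "amplitude"])
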
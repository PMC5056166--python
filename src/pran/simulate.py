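"""Synthetic lexica, frequency lists and EEG epoch sets with known ground
truth, emulating the statistical structure the analysis assumes.

The lexicon generator constructs — rather than samples — the competitor
cohort of every word-initial fragment, so realized counts equal the
recorded ground truth exactly.  Accent-2 fragments get roughly ten times
the continuations of accent-1 fragments (configured means 248.5 vs 24.8
words), with log-normal dispersion across fragments.  Distractor entries
each fail exactly one named filter (word class, initial stress,
polysyllabicity, or corpus frequency).

The EEG generator plants a boxcar effect inside the analysis window only:
windowed amplitude = study_mean + study_sd * beta * z(log C) * roi_gain,
plus subject and item offsets (also window-internal — a constant-per-epoch
offset would be removed exactly by baseline correction) and white sample
noise everywhere.  Artifacts are injected as super-threshold spikes in a
recorded epoch list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .erp import MONTAGES, EpochSet, ROISpec, montage_channels
from .lexicon import (
    DEFAULT_CONSONANTS,
    DEFAULT_VOWELS,
    CompetitionRecord,
    WIFKey,
)

__all__ = [
    "LexiconSimConfig",
    "SimulatedLexicon",
    "simulate_lexicon",
    "ErpSimConfig",
    "SimulatedEpochs",
    "simulate_epochs",
    "default_roi_gain",
]

_VOWELS = sorted(DEFAULT_VOWELS)
_UNSTRESSED_VOWELS = ("a", "e", "O", "@", "I")


@dataclass(frozen=True)
class LexiconSimConfig:
    """Conditions for the synthetic lexicon.

    Mean continuations default to the study's per-accent cohort means
    (24.8 words for accent 1, 248.5 for accent 2, a 10.0x ratio);
    ``dispersion`` is the log-space SD of the per-fragment cohort size.
    Distractor proportions are relative to the qualifying entry count.
    """

    seed: int = 0
    n_wifs: int = 26
    mean_continuations_accent1: float = 24.8
    mean_continuations_accent2: float = 248.5
    dispersion: float = 0.7
    consonants: tuple[str, ...] = DEFAULT_CONSONANTS
    p_wrong_class: float = 0.05
    p_noninitial_stress: float = 0.05
    p_monosyllabic: float = 0.05
    p_low_frequency: float = 0.05

    def __post_init__(self) -> None:
        if self.mean_continuations_accent1 <= 0 or self.mean_continuations_accent2 <= 0:
            raise ValueError("mean continuations must be positive")
        for p in (self.p_wrong_class, self.p_noninitial_stress,
                  self.p_monosyllabic, self.p_low_frequency):
            if not 0 <= p <= 1:
                raise ValueError("distractor proportions must be in [0, 1]")


@dataclass
class SimulatedLexicon:
    lexicon_text: str
    frequency_text: str
    truth: pd.DataFrame  # wif_segments, accent, count
    distractors: pd.DataFrame  # orthography, reason
    wifs: list[WIFKey]
    config: LexiconSimConfig

    def write(self, directory: str | Path) -> dict[str, Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {
            "lexicon": d / "lexicon.txt",
            "frequencies": d / "frequencies.tsv",
            "truth": d / "truth.tsv",
            "distractors": d / "distractors.tsv",
        }
        paths["lexicon"].write_text(self.lexicon_text, encoding="utf-8")
        paths["frequencies"].write_text(self.frequency_text, encoding="utf-8")
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        self.distractors.to_csv(paths["distractors"], sep="\t", index=False)
        return paths


def _distinct_prefixes(rng: np.random.Generator, n: int,
                       consonants: Sequence[str]) -> list[tuple[str, ...]]:
    """Distinct onset+vowel fragments (C V or C C V)."""
    seen: set[tuple[str, ...]] = set()
    out: list[tuple[str, ...]] = []
    n_possible = len(consonants) * len(_VOWELS) * (1 + len(consonants))
    if n > n_possible:
        raise ValueError(f"alphabet too small for {n} distinct fragments")
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n_possible:  # pragma: no cover - safety net
            raise ValueError("could not generate distinct fragments")
        onset_len = int(rng.integers(1, 3))
        onset = tuple(rng.choice(consonants) for _ in range(onset_len))
        vowel = str(rng.choice(_VOWELS))
        prefix = onset + (vowel,)
        if prefix not in seen:
            seen.add(prefix)
            out.append(prefix)
    return out


def _continuation(rng: np.random.Generator, consonants: Sequence[str]) -> list[str]:
    """Unstressed polysyllabic tail: (C V)+ with optional coda."""
    tail: list[str] = []
    for _ in range(int(rng.integers(1, 3))):
        tail.append(str(rng.choice(consonants)))
        tail.append(str(rng.choice(_UNSTRESSED_VOWELS)))
    if rng.random() < 0.5:
        tail.append(str(rng.choice(consonants)))
    return tail


def _pron(prefix: tuple[str, ...], accent: int, tail: Sequence[str]) -> str:
    onset, vowel = prefix[:-1], prefix[-1]
    return " ".join(list(onset) + [f'"{accent}', vowel] + list(tail))


def simulate_lexicon(config: LexiconSimConfig) -> SimulatedLexicon:
    """Generate a lexicon file, frequency file, and exact ground truth.

    Each of ``n_wifs`` segment prefixes occurs with both accents (as in the
    study stimuli), giving ``2 * n_wifs`` fragments.  Cohort sizes are drawn
    log-normal around the per-accent means, rounded and floored at 1, and
    then exactly that many qualifying entries are written.  Determinism:
    equal seeds give byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    prefixes = _distinct_prefixes(rng, config.n_wifs, config.consonants)
    means = {1: config.mean_continuations_accent1, 2: config.mean_continuations_accent2}
    sigma = config.dispersion
    lex_lines: list[str] = []
    freq_lines: list[str] = []
    truth_rows: list[tuple[str, int, int]] = []
    wifs: list[WIFKey] = []
    n_qualifying = 0
    for i, prefix in enumerate(prefixes):
        for accent in (1, 2):
            mu = math.log(means[accent]) - sigma * sigma / 2.0
            count = max(1, int(round(rng.lognormal(mu, sigma))))
            wifs.append(WIFKey(prefix, accent))
            truth_rows.append((" ".join(prefix), accent, count))
            for k in range(count):
                orth = f"w{accent}_{i:02d}_{k:04d}"
                lex_lines.append(f"{orth};NN;{_pron(prefix, accent, _continuation(rng, config.consonants))}")
                freq_lines.append(f"{orth}\t{int(rng.integers(2, 10_000))}")
                n_qualifying += 1

    distractor_rows: list[tuple[str, str]] = []

    def _n(p: float) -> int:
        return int(round(p * n_qualifying))

    for k in range(_n(config.p_wrong_class)):
        prefix = prefixes[int(rng.integers(len(prefixes)))]
        orth = f"dcl_{k:04d}"
        lex_lines.append(f"{orth};VB;{_pron(prefix, int(rng.integers(1, 3)), _continuation(rng, config.consonants))}")
        freq_lines.append(f"{orth}\t{int(rng.integers(2, 10_000))}")
        distractor_rows.append((orth, "wrong_class"))
    for k in range(_n(config.p_noninitial_stress)):
        prefix = prefixes[int(rng.integers(len(prefixes)))]
        orth = f"dst_{k:04d}"
        # stress lands on the second vowel: prefix vowel stays unstressed
        tail = [str(rng.choice(config.consonants)), f'"{int(rng.integers(1, 3))}',
                str(rng.choice(_VOWELS)), str(rng.choice(config.consonants))]
        pron = " ".join(list(prefix) + tail)
        lex_lines.append(f"{orth};NN;{pron}")
        freq_lines.append(f"{orth}\t{int(rng.integers(2, 10_000))}")
        distractor_rows.append((orth, "noninitial_stress"))
    for k in range(_n(config.p_monosyllabic)):
        prefix = prefixes[int(rng.integers(len(prefixes)))]
        orth = f"dmo_{k:04d}"
        coda = [str(rng.choice(config.consonants))]
        lex_lines.append(f"{orth};NN;{_pron(prefix, int(rng.integers(1, 3)), coda)}")
        freq_lines.append(f"{orth}\t{int(rng.integers(2, 10_000))}")
        distractor_rows.append((orth, "monosyllabic"))
    for k in range(_n(config.p_low_frequency)):
        prefix = prefixes[int(rng.integers(len(prefixes)))]
        orth = f"dfr_{k:04d}"
        lex_lines.append(f"{orth};NN;{_pron(prefix, int(rng.integers(1, 3)), _continuation(rng, config.consonants))}")
        f = int(rng.integers(0, 2))
        if f > 0:  # frequency 0 words are simply absent from the list
            freq_lines.append(f"{orth}\t{f}")
        distractor_rows.append((orth, "low_frequency"))

    order = rng.permutation(len(lex_lines))
    lex_text = "\n".join(lex_lines[j] for j in order) + "\n"
    freq_text = "\n".join(freq_lines) + "\n"
    return SimulatedLexicon(
        lexicon_text=lex_text,
        frequency_text=freq_text,
        truth=pd.DataFrame(truth_rows, columns=["wif_segments", "accent", "count"]),
        distractors=pd.DataFrame(distractor_rows, columns=["orthography", "reason"]),
        wifs=wifs,
        config=config,
    )


def default_roi_gain(montage: Sequence[ROISpec]) -> dict[str, float]:
    """Left-lateralized competition-effect topography: full gain over the
    left hemisphere, attenuated elsewhere."""
    return {r.name: (1.0 if r.laterality == "left" else 0.25) for r in montage}


@dataclass(frozen=True)
class ErpSimConfig:
    """Conditions for the synthetic EEG.

    Defaults follow the first study's configuration: 18 subjects, the
    6-ROI montage, 250 Hz sampling over -200..280 ms, competition slope
    beta = 0.387 on z(log C) in study-SD units (study mean -2.44 uV, SD
    0.91 uV), and noise calibrated so the standardized simple regression
    attains R-squared near ``target_r2`` (0.15).  ``item_sd`` overrides the
    calibration when given; with beta = 0 a fallback of 0.9 * study_sd is
    used.  SDs are microvolts.
    """

    seed: int = 0
    n_subjects: int = 18
    montage: str = "exp1_3"
    sfreq: float = 250.0
    tmin: float = -200.0
    tmax: float = 280.0
    window: tuple[float, float] = (136.0, 280.0)
    beta: float = 0.387
    study_mean: float = -2.44
    study_sd: float = 0.91
    target_r2: float = 0.15
    roi_gain: dict[str, float] | None = None
    subject_sd: float = 2.0
    item_sd: float | None = None
    sample_noise_sd: float = 5.0
    baseline_drift_sd: float = 5.0
    artifact_rate: float = 0.0
    artifact_threshold: float = 100.0

    def resolved_item_sd(self) -> float:
        if self.item_sd is not None:
            return self.item_sd
        if self.beta == 0 or not (0 < self.target_r2 < 1):
            return 0.9 * self.study_sd
        return self.study_sd * abs(self.beta) * math.sqrt(
            (1 - self.target_r2) / self.target_r2
        )


@dataclass
class EpochTruth:
    beta: float
    subject_offsets: np.ndarray
    item_offsets: np.ndarray
    artifacts: list[tuple[str, str]]  # (subject, item)


@dataclass
class SimulatedEpochs:
    epochs: EpochSet
    truth: EpochTruth
    config: ErpSimConfig


def simulate_epochs(
    config: ErpSimConfig, competition: Sequence[CompetitionRecord]
) -> SimulatedEpochs:
    """Simulate one epoch per subject x WIF item with a planted competition
    effect.  Competition records must carry ``z_log_count``."""
    montage = MONTAGES[config.montage]
    channels = montage_channels(montage)
    gains = config.roi_gain or default_roi_gain(montage)
    missing = [r.name for r in montage if r.name not in gains]
    if missing:
        raise ValueError(f"roi_gain missing ROI(s): {', '.join(missing)}")
    chan_gain = np.array(
        [gains[roi.name] for roi in montage for _ in roi.channels], dtype=float
    )
    if list(channels) != [c for roi in montage for c in roi.channels]:  # pragma: no cover
        raise AssertionError("channel order out of sync with montage")
    rng = np.random.default_rng(config.seed)
    records = sorted(competition, key=lambda r: r.wif)
    n_s = config.n_subjects
    n_i = len(records)
    n_c = len(channels)
    dt = 1000.0 / config.sfreq
    times = np.arange(config.tmin, config.tmax + dt / 2, dt)
    n_t = len(times)
    z = np.array([r.z_log_count for r in records])

    amp = rng.normal(0.0, config.sample_noise_sd, size=(n_s, n_i, n_c, n_t))
    amp += rng.normal(0.0, config.baseline_drift_sd, size=(n_s, n_i, n_c))[..., None]
    subject_offsets = rng.normal(0.0, config.subject_sd, size=n_s)
    item_offsets = rng.normal(0.0, config.resolved_item_sd(), size=n_i)
    lo, hi = config.window
    wmask = (times >= lo) & (times <= hi)
    signal = (
        config.study_mean
        + config.study_sd * config.beta * z[None, :, None] * chan_gain[None, None, :]
        + subject_offsets[:, None, None]
        + item_offsets[None, :, None]
    )
    amp[..., wmask] += signal[..., None]

    subjects = [f"s{k:02d}" for k in range(n_s)]
    items = [f"i{k:03d}" for k in range(n_i)]
    artifacts: list[tuple[str, str]] = []
    n_art = int(round(config.artifact_rate * n_s * n_i))
    if n_art:
        flat = rng.choice(n_s * n_i, size=n_art, replace=False)
        spike = config.artifact_threshold + 50.0
        for f in sorted(flat):
            si, ii = divmod(int(f), n_i)
            ci = int(rng.integers(n_c))
            ti = int(rng.integers(n_t))
            amp[si, ii, ci, ti] = spike * (1 if rng.random() < 0.5 else -1)
            artifacts.append((subjects[si], items[ii]))

    item_wif = {items[k]: records[k].wif for k in range(n_i)}
    epochs = EpochSet(amp, times, list(channels), subjects, items, item_wif)
    return SimulatedEpochs(
        epochs,
        EpochTruth(config.beta, subject_offsets, item_offsets, artifacts),
        config,
    )
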
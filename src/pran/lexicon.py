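"""Pronunciation-lexicon parsing and word-initial-fragment (WIF) competition scores.

A WIF is the initial segment string of a word up to and including its first
vowel, which must carry primary stress, together with the word accent
(Swedish accent 1 or accent 2) realized on that vowel.  The lexical
competition of a WIF is the number of lexicon word forms that share it under
the study constraints: nouns, polysyllabic, initial-syllable stress, corpus
frequency at or above a threshold.  The carrier word counts in its own
cohort.

The pronunciation dialect parsed here is whitespace-tokenized: segment
symbols, the markers ``"1`` / ``"2`` (accent-1 / accent-2 primary stress,
attaching to the next vowel token) and ``$`` (syllable boundary, ignored).
Real lexica with other field layouts are mapped in via ``column_map``.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_VOWELS",
    "DEFAULT_CONSONANTS",
    "ACCENT_MARKERS",
    "SYLLABLE_MARK",
    "MalformedPronunciationError",
    "UnattestedWIFError",
    "DegenerateCompetitionWarning",
    "WIFKey",
    "PronEntry",
    "FrequencyTable",
    "Constraints",
    "CompetitionRecord",
    "ParseReport",
    "parse_pronunciation",
    "parse_lexicon",
    "parse_frequency_table",
    "apply_frequency_filter",
    "extract_wif",
    "count_competitors",
    "competitor_index",
    "competition_table",
    "accent_continuation_ratio",
    "wif_token_frequency",
    "write_competition_table",
    "read_competition_table",
]

# Swedish-like SAMPA-style inventory used by the synthetic lexica and by the
# default parser configuration.  Any symbol set can be supplied instead.
DEFAULT_VOWELS = frozenset(
    {
        "i:", "I", "y:", "Y", "e:", "e", "E:", "E", "a", "A:",
        "o:", "O", "u:", "U", "u0", "2:", "9", "@",
    }
)
DEFAULT_CONSONANTS = (
    "p", "b", "t", "d", "k", "g", "f", "v", "s", "S",
    "h", "j", "l", "r", "m", "n", "N",
)

ACCENT_MARKERS: Mapping[str, int] = {'"1': 1, '"2': 2}
SYLLABLE_MARK = "$"


class MalformedPronunciationError(ValueError):
    """A pronunciation string violates the marker grammar."""


class UnattestedWIFError(ValueError):
    """A queried WIF has no competitors in the (filtered) lexicon."""


class DegenerateCompetitionWarning(UserWarning):
    """All competitor counts are equal; z-scores are emitted as zeros."""


@dataclass(frozen=True, order=True)
class WIFKey:
    """Competition unit: segments up to and including the stressed first vowel,
    plus word accent.  Equality and ordering are over (segments, accent)."""

    segments: tuple[str, ...]
    accent: int

    def __post_init__(self) -> None:
        if self.accent not in (1, 2):
            raise ValueError(f"accent must be 1 or 2, got {self.accent!r}")

    @property
    def label(self) -> str:
        return " ".join(self.segments) + f"+{self.accent}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


@dataclass
class PronEntry:
    """One lexicon word form."""

    orthography: str
    word_class: str
    segments: tuple[str, ...]
    stress_index: int | None
    accent: int | None
    syllable_count: int
    frequency: int = 0


@dataclass
class FrequencyTable:
    """Orthography -> corpus count; unlisted words count 0."""

    counts: dict[str, int] = field(default_factory=dict)
    min_frequency: int = 2

    def get(self, orthography: str) -> int:
        return self.counts.get(orthography, 0)


@dataclass(frozen=True)
class Constraints:
    """Which lexicon entries qualify as competitors."""

    word_class: str | None = "NN"
    polysyllabic: bool = True
    initial_stress: bool = True


@dataclass
class CompetitionRecord:
    wif: WIFKey
    count: int
    log_count: float
    z_log_count: float
    group: str = "unassigned"


@dataclass
class ParseReport:
    n_lines: int = 0
    n_parsed: int = 0
    n_skipped: int = 0
    messages: list[str] = field(default_factory=list)


DEFAULT_COLUMN_MAP: Mapping[str, int] = {
    "orthography": 0,
    "word_class": 1,
    "pronunciation": 2,
}


def parse_pronunciation(
    pron: str, vowels: frozenset[str] | set[str] = DEFAULT_VOWELS
) -> tuple[tuple[str, ...], int | None, int | None, int]:
    """Tokenize one pronunciation string.

    Returns ``(segments, stress_index, accent, syllable_count)``.  Stress
    markers attach to the next vowel token; ``$`` is ignored.  Raises
    :class:`MalformedPronunciationError` on a second marker or on a marker
    not followed by any vowel.
    """
    segments: list[str] = []
    stress_index: int | None = None
    accent: int | None = None
    pending: int | None = None
    for tok in pron.split():
        if tok in ACCENT_MARKERS:
            if accent is not None or pending is not None:
                raise MalformedPronunciationError(
                    f"more than one stress marker in {pron!r}"
                )
            pending = ACCENT_MARKERS[tok]
        elif tok == SYLLABLE_MARK:
            continue
        else:
            segments.append(tok)
            if pending is not None and tok in vowels:
                stress_index = len(segments) - 1
                accent = pending
                pending = None
    if pending is not None:
        raise MalformedPronunciationError(
            f"stress marker not followed by a vowel in {pron!r}"
        )
    syllable_count = sum(s in vowels for s in segments)
    return tuple(segments), stress_index, accent, syllable_count


def parse_lexicon(
    path: str | Path,
    column_map: Mapping[str, int] | None = None,
    delimiter: str = ";",
    vowels: frozenset[str] | set[str] = DEFAULT_VOWELS,
) -> tuple[list[PronEntry], ParseReport]:
    """Parse a delimited lexicon file into :class:`PronEntry` records.

    ``column_map`` names the 0-based field indices of orthography, word class
    and pronunciation (default: fields 0, 1, 2), which makes wide formats
    such as the 51-field NST layout usable by pointing at the right columns.
    Malformed lines are skipped and counted in the returned report.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    for key in ("orthography", "word_class", "pronunciation"):
        if key not in cmap:
            raise ValueError(f"column_map is missing {key!r}")
    report = ParseReport()
    entries: list[PronEntry] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        report.n_lines += 1
        fields = line.split(delimiter)
        needed = max(cmap.values())
        if needed >= len(fields):
            report.n_skipped += 1
            report.messages.append(
                f"line {lineno}: only {len(fields)} fields, need index {needed}"
            )
            continue
        orth = fields[cmap["orthography"]].strip()
        wclass = fields[cmap["word_class"]].strip()
        pron = fields[cmap["pronunciation"]].strip()
        if not orth or not pron:
            report.n_skipped += 1
            report.messages.append(f"line {lineno}: empty orthography or pronunciation")
            continue
        try:
            segments, stress_index, accent, nsyll = parse_pronunciation(pron, vowels)
        except MalformedPronunciationError as exc:
            report.n_skipped += 1
            report.messages.append(f"line {lineno}: {exc}")
            continue
        entries.append(
            PronEntry(orth, wclass, segments, stress_index, accent, nsyll)
        )
        report.n_parsed += 1
    return entries, report


def parse_frequency_table(
    path: str | Path, delimiter: str = "\t", min_frequency: int = 2
) -> FrequencyTable:
    """Read a two-column (orthography, count) frequency list."""
    counts: dict[str, int] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        word, _, count = line.partition(delimiter)
        counts[word.strip()] = int(count)
    table = FrequencyTable(counts, min_frequency=min_frequency)
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative corpus count in frequency table")
    return table


def apply_frequency_filter(
    entries: Sequence[PronEntry], freq: FrequencyTable
) -> list[PronEntry]:
    """Keep entries whose orthography meets the corpus-frequency threshold.

    Each surviving entry's ``frequency`` field is filled in; order preserved.
    """
    kept: list[PronEntry] = []
    for entry in entries:
        f = freq.get(entry.orthography)
        if f >= freq.min_frequency:
            entry.frequency = f
            kept.append(entry)
    return kept


def extract_wif(
    entry: PronEntry, vowels: frozenset[str] | set[str] = DEFAULT_VOWELS
) -> WIFKey | None:
    """The entry's WIF, or None when the entry has no accent/stress or the
    stress is not on the first vowel (initial-syllable stress required)."""
    if entry.accent not in (1, 2) or entry.stress_index is None:
        return None
    if any(s in vowels for s in entry.segments[: entry.stress_index]):
        return None
    return WIFKey(tuple(entry.segments[: entry.stress_index + 1]), entry.accent)


def _qualifies(
    entry: PronEntry, constraints: Constraints, vowels: frozenset[str] | set[str]
) -> bool:
    if constraints.word_class is not None and entry.word_class != constraints.word_class:
        return False
    if constraints.polysyllabic and entry.syllable_count < 2:
        return False
    if constraints.initial_stress and extract_wif(entry, vowels) is None:
        return False
    return True


def count_competitors(
    wif: WIFKey,
    entries: Iterable[PronEntry],
    constraints: Constraints = Constraints(),
    vowels: frozenset[str] | set[str] = DEFAULT_VOWELS,
) -> int:
    """Cohort size of ``wif``: entries sharing its segments AND accent that
    satisfy the constraints.  0 is legal for an absent WIF."""
    n = 0
    for entry in entries:
        if _qualifies(entry, constraints, vowels) and extract_wif(entry, vowels) == wif:
            n += 1
    return n


def competitor_index(
    entries: Iterable[PronEntry],
    constraints: Constraints = Constraints(),
    vowels: frozenset[str] | set[str] = DEFAULT_VOWELS,
) -> Counter[WIFKey]:
    """Competitor counts for every WIF attested by qualifying entries."""
    counts: Counter[WIFKey] = Counter()
    for entry in entries:
        if not _qualifies(entry, constraints, vowels):
            continue
        wif = extract_wif(entry, vowels)
        if wif is not None:
            counts[wif] += 1
    return counts


def competition_table(
    wifs: Sequence[WIFKey],
    entries: Sequence[PronEntry],
    constraints: Constraints = Constraints(),
    vowels: frozenset[str] | set[str] = DEFAULT_VOWELS,
    log_base: float = math.e,
) -> list[CompetitionRecord]:
    """Competitor counts with log and z transforms for a set of query WIFs.

    z-scores are standardized over exactly the supplied WIF set with sample
    SD (n-1).  The log base is immaterial to the z-scores; natural log is the
    declared default for the stored ``log_count``.  Output is sorted by WIF
    key.  Raises :class:`UnattestedWIFError` on a WIF with no competitors.
    """
    if not wifs:
        raise ValueError("wifs must be non-empty")
    index = competitor_index(entries, constraints, vowels)
    ordered = sorted(set(wifs))
    counts = []
    for wif in ordered:
        c = index.get(wif, 0)
        if c < 1:
            raise UnattestedWIFError(f"WIF {wif.label} is not attested in the lexicon")
        counts.append(c)
    logs = np.log(np.asarray(counts, dtype=float)) / math.log(log_base)
    sd = float(np.std(logs, ddof=1)) if len(logs) > 1 else 0.0
    if sd == 0.0:
        warnings.warn(
            "all competitor counts equal; z-scores set to 0",
            DegenerateCompetitionWarning,
            stacklevel=2,
        )
        z = np.zeros_like(logs)
    else:
        z = (logs - logs.mean()) / sd
    return [
        CompetitionRecord(wif, int(c), float(lg), float(zz))
        for wif, c, lg, zz in zip(ordered, counts, logs, z)
    ]


def accent_continuation_ratio(
    entries: Sequence[PronEntry],
    constraints: Constraints = Constraints(),
    vowels: frozenset[str] | set[str] = DEFAULT_VOWELS,
) -> float:
    """Mean competitor count of accent-2 WIFs divided by that of accent-1
    WIFs, over the WIF inventory induced by the lexicon."""
    index = competitor_index(entries, constraints, vowels)
    by_accent: dict[int, list[int]] = {1: [], 2: []}
    for wif, c in index.items():
        by_accent[wif.accent].append(c)
    if not by_accent[1]:
        raise ValueError("no accent-1 WIFs attested; ratio undefined")
    if not by_accent[2]:
        raise ValueError("no accent-2 WIFs attested; ratio undefined")
    return float(np.mean(by_accent[2]) / np.mean(by_accent[1]))


def wif_token_frequency(
    wifs: Sequence[WIFKey],
    entries: Sequence[PronEntry],
    constraints: Constraints = Constraints(),
    vowels: frozenset[str] | set[str] = DEFAULT_VOWELS,
) -> dict[WIFKey, float]:
    """Mean corpus frequency of each WIF's qualifying competitor words.

    The mean (not the sum) is used so that the frequency covariate measures
    how common the words carrying a WIF are, independently of how many of
    them there are — the summed cohort frequency would be confounded with
    the competitor count itself.  Entries must already carry frequencies
    (see :func:`apply_frequency_filter`)."""
    wanted = set(wifs)
    totals: dict[WIFKey, float] = {w: 0.0 for w in wanted}
    counts: dict[WIFKey, int] = {w: 0 for w in wanted}
    for entry in entries:
        if not _qualifies(entry, constraints, vowels):
            continue
        wif = extract_wif(entry, vowels)
        if wif in totals:
            totals[wif] += entry.frequency
            counts[wif] += 1
    return {w: (totals[w] / counts[w] if counts[w] else 0.0) for w in wanted}


def write_competition_table(records: Sequence[CompetitionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "wif_segments": [" ".join(r.wif.segments) for r in records],
            "accent": [r.wif.accent for r in records],
            "count": [r.count for r in records],
            "log_count": [r.log_count for r in records],
            "z_log_count": [r.z_log_count for r in records],
            "group": [r.group for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_competition_table(path: str | Path) -> list[CompetitionRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for segs, accent, count, log_count, z, group in df[
        ["wif_segments", "accent", "count", "log_count", "z_log_count", "group"]
    ].itertuples(index=False, name=None):
        wif = WIFKey(tuple(str(segs).split()), int(accent))
        records.append(
            CompetitionRecord(wif, int(count), float(log_count), float(z), str(group))
        )
    return records
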
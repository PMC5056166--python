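"""Independent oracles used by the test suite.

These deliberately re-derive results through different code paths than the
package: competitor counting by a literal double loop over entries,
repeated-measures ANOVA through statsmodels' AnovaRM, and correlations via
numpy.  They must never call the package functions they check.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM

from pran.lexicon import DEFAULT_VOWELS, PronEntry


def brute_force_count(
    wif_segments: Sequence[str],
    accent: int,
    entries: Iterable[PronEntry],
    vowels=DEFAULT_VOWELS,
    word_class: str | None = "NN",
    polysyllabic: bool = True,
) -> int:
    """Competitor count by direct enumeration, re-deriving each entry's WIF
    from its segment/stress fields without the package's helpers."""
    target = tuple(wif_segments)
    n = 0
    for e in entries:
        if word_class is not None and e.word_class != word_class:
            continue
        if polysyllabic and e.syllable_count < 2:
            continue
        if e.accent != accent or e.stress_index is None:
            continue
        first_vowel = None
        for i, seg in enumerate(e.segments):
            if seg in vowels:
                first_vowel = i
                break
        if first_vowel is None or first_vowel != e.stress_index:
            continue
        if tuple(e.segments[: first_vowel + 1]) != target:
            continue
        n += 1
    return n


def anova_oracle(
    data: pd.DataFrame,
    dv: str = "amplitude",
    subject: str = "subject",
    within: Sequence[str] = ("competitors",),
) -> dict[frozenset[str], tuple[float, int, int, float]]:
    """AnovaRM results keyed by the set of factors in each effect:
    {factors} -> (F, df_num, df_den, p)."""
    res = AnovaRM(data, dv, subject, within=list(within)).fit()
    out: dict[frozenset[str], tuple[float, int, int, float]] = {}
    for name, row in res.anova_table.iterrows():
        key = frozenset(str(name).split(":"))
        out[key] = (
            float(row["F Value"]),
            int(round(row["Num DF"])),
            int(round(row["Den DF"])),
            float(row["Pr > F"]),
        )
    return out


def grand_average_oracle(amplitudes, rejected, item_wif_indices, n_wifs):
    """Nested-loop two-stage WIF averaging over a (S, I, C, T) array."""
    n_s, n_i, n_c, n_t = amplitudes.shape
    out = np.full((n_wifs, n_c, n_t), np.nan)
    for w in range(n_wifs):
        per_subject = []
        for s in range(n_s):
            traces = [
                amplitudes[s, i]
                for i in range(n_i)
                if item_wif_indices[i] == w and not rejected[s, i]
            ]
            if traces:
                per_subject.append(np.mean(traces, axis=0))
        if per_subject:
            out[w] = np.mean(per_subject, axis=0)
    return out
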
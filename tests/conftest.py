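import numpy as np
import pytest

from pran.erp import EpochSet
from pran.lexicon import (
    Constraints,
    PronEntry,
    WIFKey,
    competition_table,
    parse_pronunciation,
)
from pran.simulate import LexiconSimConfig, simulate_lexicon

# small but non-trivial lexicon conditions used across tests
SMALL_LEXCFG = LexiconSimConfig(
    seed=7, n_wifs=8, mean_continuations_accent1=5.0,
    mean_continuations_accent2=50.0,
)


def entry(orth: str, pron: str, word_class: str = "NN", frequency: int = 10) -> PronEntry:
    segments, stress, accent, nsyll = parse_pronunciation(pron)
    return PronEntry(orth, word_class, segments, stress, accent, nsyll, frequency)


@pytest.fixture(scope="session")
def toy_entries() -> list[PronEntry]:
    """3 accent-1 and 5 accent-2 polysyllabic nouns sharing [b, o:], plus
    entries that fail one constraint each."""
    shared1 = [entry(f"a1_{k}", 'b "1 o: t a r') for k in range(3)]
    shared2 = [entry(f"a2_{k}", 'b "2 o: t h u: s') for k in range(5)]
    other = [
        entry("fisk", 'f "1 I s k a r'),
        entry("verb", 'b "1 o: t a', word_class="VB"),
        entry("mono", 'b "1 o: t'),
        entry("late", 'b a t "1 o: n'),
        entry("bare", "b o: t a"),
    ]
    return shared1 + shared2 + other


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_lexicon(SMALL_LEXCFG)


@pytest.fixture(scope="session")
def small_entries(small_bundle):
    from pran.lexicon import apply_frequency_filter, parse_frequency_table, parse_lexicon
    import tempfile, pathlib

    d = pathlib.Path(tempfile.mkdtemp())
    paths = small_bundle.write(d)
    entries, report = parse_lexicon(paths["lexicon"])
    assert report.n_skipped == 0
    return apply_frequency_filter(entries, parse_frequency_table(paths["frequencies"]))


@pytest.fixture(scope="session")
def small_records(small_bundle, small_entries):
    return competition_table(small_bundle.wifs, small_entries, Constraints())


def make_epochs(
    amplitudes: np.ndarray,
    times: np.ndarray | None = None,
    channels: list[str] | None = None,
    wif_of_item: list[WIFKey] | None = None,
) -> EpochSet:
    """Wrap a raw (S, I, C, T) array into an EpochSet with generic labels."""
    n_s, n_i, n_c, n_t = amplitudes.shape
    if times is None:
        times = np.arange(-200.0, 281.0, 4.0)[:n_t]
    if channels is None:
        channels = [f"CH{k}" for k in range(n_c)]
    subjects = [f"s{k}" for k in range(n_s)]
    items = [f"i{k}" for k in range(n_i)]
    if wif_of_item is None:
        wif_of_item = [WIFKey((f"k{k}", "a"), 1) for k in range(n_i)]
    item_wif = {items[k]: wif_of_item[k] for k in range(n_i)}
    return EpochSet(amplitudes, times, channels, subjects, items, item_wif)
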
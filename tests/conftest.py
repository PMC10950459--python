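"""Shared fixtures: tiny hand-built songs and seeded random corpora."""

from datetime import date

import numpy as np
import pytest

from evosig.corpus import ChordSymbol, Corpus, Song, Tonality, PITCH_CLASS


def chord(label: str) -> ChordSymbol:
    """'C' -> C major, 'Am' -> A minor (test shorthand)."""
    minor = label.endswith("m")
    root = label[:-1] if minor else label
    return ChordSymbol(PITCH_CLASS[root], 1 if minor else 0)


def make_song(labels, tonic="C", mode=0, song_id="s", day=0,
              formal=(), genres=()):
    return Song(
        id=song_id,
        chords=[chord(lab) for lab in labels],
        tonality=Tonality(PITCH_CLASS[tonic], mode),
        date=date(1960, 1, 1) if day == 0 else date.fromordinal(
            date(1960, 1, 1).toordinal() + day),
        formal=list(formal),
        genres=frozenset(genres),
    )


def random_song(rng: np.random.Generator, length=None, song_id="r",
                day=0) -> Song:
    length = length if length is not None else int(rng.integers(1, 15))
    chords = [ChordSymbol(int(rng.integers(12)), int(rng.integers(2)))
              for _ in range(length)]
    return Song(id=song_id, chords=chords,
                tonality=Tonality(int(rng.integers(12)), int(rng.integers(2))),
                date=date.fromordinal(date(1960, 1, 1).toordinal() + day))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_corpus():
    """Six dated songs with formal sections and genres."""
    songs = [
        make_song(["C", "F", "G", "C"], song_id=f"song{i}", day=i * 30,
                  formal=["verse", "chorus", "verse", "chorus"],
                  genres=("rock",) if i % 2 else ("pop",))
        for i in range(6)
    ]
    return Corpus(songs)
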
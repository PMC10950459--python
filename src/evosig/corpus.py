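"""Symbolic song corpora: types, reading/writing, preprocessing, partitioning.

A corpus is a date-ordered collection of songs.  Each song carries an
ordered chord sequence (root pitch-class 0-11, quality major/minor), a
tonality (tonic pitch-class + mode), an optional formal-section label
sequence (verse/chorus/...), a date used for chronological ranking, and an
optional set of genre labels.

Pitch classes follow the flat-name convention Ab=0, A=1, Bb=2, B=3, C=4,
Db=5, D=6, Eb=7, E=8, F=9, Gb=10, G=11; sharp spellings are mapped
enharmonically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date as _date
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Pitch-class integers for flat-convention note names (Ab=0, A=1, ...).
PITCH_CLASS: dict[str, int] = {
    "Ab": 0, "A": 1, "Bb": 2, "B": 3, "C": 4, "Db": 5,
    "D": 6, "Eb": 7, "E": 8, "F": 9, "Gb": 10, "G": 11,
    # enharmonic sharp / irregular spellings
    "G#": 0, "A#": 2, "B#": 4, "C#": 5, "D#": 7, "E#": 9, "F#": 10,
    "Cb": 3, "Fb": 8,
}

PITCH_NAME: tuple[str, ...] = (
    "Ab", "A", "Bb", "B", "C", "Db", "D", "Eb", "E", "F", "Gb", "G",
)

MAJOR, MINOR = 0, 1

#: Sentinel returned by :func:`normalize_chord_label` for chords outside the
#: active quality policy (diminished, augmented, power chords, ...).
DROP = object()

#: Default quality policy: suffix (lower-cased, after the root) -> quality.
#: Suffixes absent from the table map to the drop-marker.  Extensions such
#: as 7ths/9ths/inversions are collapsed onto plain major/minor.
DEFAULT_QUALITY_POLICY: dict[str, int] = {
    "maj": MAJOR, "maj7": MAJOR, "maj6": MAJOR, "maj9": MAJOR, "6": MAJOR,
    "7": MAJOR, "9": MAJOR, "11": MAJOR, "13": MAJOR, "add9": MAJOR,
    "sus": MAJOR, "sus2": MAJOR, "sus4": MAJOR,
    "min": MINOR, "m": MINOR, "min6": MINOR, "min7": MINOR, "min9": MINOR,
    "min11": MINOR, "m7": MINOR, "m6": MINOR, "m9": MINOR,
}


class CorpusFormatError(ValueError):
    """Raised when a corpus file does not conform to the documented layout."""


@dataclass(frozen=True)
class ChordSymbol:
    """A chord reduced to root pitch-class and major/minor quality."""

    root: int
    quality: int

    def __post_init__(self) -> None:
        if not 0 <= self.root <= 11:
            raise ValueError(f"root {self.root} outside 0..11")
        if self.quality not in (MAJOR, MINOR):
            raise ValueError(f"quality {self.quality} not in {{0,1}}")

    @property
    def label(self) -> str:
        return PITCH_NAME[self.root] + (":min" if self.quality else ":maj")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ChordSymbol({self.label})"


@dataclass(frozen=True)
class Tonality:
    """Tonic pitch-class and mode (0 = major, 1 = minor)."""

    tonic: int
    mode: int

    def __post_init__(self) -> None:
        if not 0 <= self.tonic <= 11:
            raise ValueError(f"tonic {self.tonic} outside 0..11")
        if self.mode not in (MAJOR, MINOR):
            raise ValueError(f"mode {self.mode} not in {{0,1}}")


@dataclass
class Song:
    id: str
    chords: list[ChordSymbol]
    tonality: Tonality
    date: _date
    formal: list[str] = field(default_factory=list)
    genres: frozenset[str] = frozenset()


@dataclass
class Corpus:
    """Date-sorted song collection; ties in date broken by song id."""

    songs: list[Song]

    def __post_init__(self) -> None:
        self.songs = sorted(self.songs, key=lambda s: (s.date, s.id))

    def __len__(self) -> int:
        return len(self.songs)

    def __iter__(self):
        return iter(self.songs)

    def __getitem__(self, i: int) -> Song:
        return self.songs[i]

    @property
    def genre_vocabulary(self) -> list[str]:
        return sorted({g for s in self.songs for g in s.genres})

    @property
    def formal_vocabulary(self) -> list[str]:
        return sorted({c for s in self.songs for c in s.formal})


def normalize_chord_label(label: str, policy: dict[str, int] | None = None):
    """Map a chord label like ``"C:maj7"`` to a :class:`ChordSymbol`.

    The root is resolved via the Ab=0 convention; the suffix after ``:`` is
    collapsed to major/minor through ``policy`` (default
    :data:`DEFAULT_QUALITY_POLICY`).  Labels whose suffix is outside the
    policy (or missing) return the module-level :data:`DROP` marker; an
    unrecognizable root raises ``ValueError``.
    """
    policy = DEFAULT_QUALITY_POLICY if policy is None else policy
    root_part, _, qual_part = label.partition(":")
    root_part = root_part.strip()
    key = root_part[:1].upper() + root_part[1:].lower() if root_part else root_part
    if key not in PITCH_CLASS:
        raise ValueError(f"unrecognizable chord root in label {label!r}")
    quality = policy.get(qual_part.strip().lower(), DROP)
    if quality is DROP:
        return DROP
    return ChordSymbol(PITCH_CLASS[key], quality)


def dedup_repeats(chords: list[ChordSymbol]) -> list[ChordSymbol]:
    """Collapse maximal runs of identical consecutive chords to one symbol."""
    out: list[ChordSymbol] = []
    for c in chords:
        if not out or out[-1] != c:
            out.append(c)
    return out


def _parse_tonality(tonic_raw, mode_raw) -> Tonality:
    tonic_s = str(tonic_raw).strip()
    if tonic_s.lstrip("-").isdigit():
        tonic = int(tonic_s)
    else:
        key = tonic_s[:1].upper() + tonic_s[1:].lower()
        if key not in PITCH_CLASS:
            raise ValueError(f"unrecognizable tonic {tonic_raw!r}")
        tonic = PITCH_CLASS[key]
    mode_s = str(mode_raw).strip().lower()
    mode = {"maj": MAJOR, "major": MAJOR, "0": MAJOR,
            "min": MINOR, "minor": MINOR, "1": MINOR}.get(mode_s)
    if mode is None:
        raise ValueError(f"unrecognizable mode {mode_raw!r}")
    return Tonality(tonic, mode)


REQUIRED_COLUMNS = ("id", "date", "tonic", "mode", "chords")


def read_corpus(path, policy: dict[str, int] | None = None,
                dedup: bool = True) -> Corpus:
    """Read a corpus from a delimited table or a JSON-lines mirror.

    Layout: columns ``id, date (ISO-8601), tonic (name or 0-11),
    mode (maj|min|0|1), chords (space-separated labels),
    formal (space-separated, optional), genres (semicolon-separated,
    optional)``.  Chord labels outside the quality policy are dropped with
    a per-song warning; consecutive-repeat pruning is applied unless
    ``dedup=False``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".jsonl", ".ndjson"):
        rows = [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"missing required column(s): {missing}")

    songs: list[Song] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        sid = str(row.id)
        try:
            date = _date.fromisoformat(str(row.date).strip())
        except ValueError as exc:
            raise CorpusFormatError(
                f"row {row_no} (song {sid!r}): unparseable date {row.date!r}"
            ) from exc
        tonality = _parse_tonality(row.tonic, row.mode)
        chords: list[ChordSymbol] = []
        for lab in str(row.chords).split():
            sym = normalize_chord_label(lab, policy)
            if sym is DROP:
                logger.warning("song %s: dropped chord label %r (quality policy)",
                               sid, lab)
            else:
                chords.append(sym)
        formal = str(getattr(row, "formal", "") or "").split()
        genres = frozenset(
            g.strip() for g in str(getattr(row, "genres", "") or "").split(";")
            if g.strip()
        )
        songs.append(Song(sid, dedup_repeats(chords) if dedup else chords,
                          tonality, date, formal, genres))
    if not songs:
        raise CorpusFormatError(f"empty corpus: {path}")
    return Corpus(songs)


def write_corpus(corpus: Corpus, path) -> None:
    """Write a corpus in the tabular layout accepted by :func:`read_corpus`."""
    path = Path(path)
    rows = []
    for s in corpus:
        rows.append({
            "id": s.id,
            "date": s.date.isoformat(),
            "tonic": s.tonality.tonic,
            "mode": "min" if s.tonality.mode else "maj",
            "chords": " ".join(c.label for c in s.chords),
            "formal": " ".join(s.formal),
            "genres": ";".join(sorted(s.genres)),
        })
    if path.suffix in (".jsonl", ".ndjson"):
        path.write_text("\n".join(json.dumps(r) for r in rows) + "\n")
    else:
        pd.DataFrame(rows).to_csv(path, index=False)


def chronological_split(corpus: Corpus, stride: int = 5) -> tuple[Corpus, Corpus]:
    """Hold out every ``stride``-th song (1-based positions stride, 2*stride,
    ...) in date order as a test set; the remainder is the training set."""
    if stride < 2:
        raise ValueError(f"stride must be >= 2, got {stride}")
    test = [s for pos, s in enumerate(corpus, start=1) if pos % stride == 0]
    train = [s for pos, s in enumerate(corpus, start=1) if pos % stride != 0]
    return Corpus(train), Corpus(test)


def deduplicate_songs(corpus: Corpus, key=None) -> Corpus:
    """Retain one song per identity key (default: case-folded id); the
    earliest-dated copy wins, with id as deterministic tie-break."""
    key = key or (lambda s: s.id.casefold())
    best: dict[object, Song] = {}
    for s in corpus:  # corpus is (date, id)-sorted, so first seen = earliest
        best.setdefault(key(s), s)
    removed = len(corpus) - len(best)
    if removed:
        logger.info("deduplicate_songs: removed %d duplicate song(s)", removed)
    return Corpus(list(best.values()))


def transpose_song(song: Song, interval: int) -> Song:
    """Jointly transpose a song's chords and tonic by ``interval`` semitones
    (used by key-invariance checks)."""
    chords = [ChordSymbol((c.root + interval) % 12, c.quality) for c in song.chords]
    ton = Tonality((song.tonality.tonic + interval) % 12, song.tonality.mode)
    return replace(song, chords=chords, tonality=ton)
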
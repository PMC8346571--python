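"""Per-base coverage containers for strand-specific IP-seq libraries.

Every library in the workflow (input, cap-m7G IP, and the FTO(-)/FTO(+)
m6A-IP pair) is represented as dense per-contig, per-strand arrays of
read depth and read 5'-end counts ("starts"), together with the total
number of mapped reads of the library.  All coordinates are 0-based
half-open; a track never mixes strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

STRANDS = ("+", "-")

# Library roles of the four sequenced samples per condition.
ROLE_INPUT = "input"
ROLE_M7G = "m7g_ip"
ROLE_FTO_MINUS = "fto_minus"
ROLE_FTO_PLUS = "fto_plus"
ALL_ROLES = (ROLE_INPUT, ROLE_M7G, ROLE_FTO_MINUS, ROLE_FTO_PLUS)


class ConsistencyError(ValueError):
    """Raised when depth/starts arrays violate the track contract."""


@dataclass
class BaseTrack:
    """Depth and read-start counts for one contig on one strand."""

    contig: str
    strand: str
    depth: np.ndarray
    starts: np.ndarray

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        if self.depth.shape != self.starts.shape:
            raise ConsistencyError(
                f"{self.contig}:{self.strand}: depth and starts lengths differ "
                f"({self.depth.size} vs {self.starts.size})"
            )
        if (self.depth < 0).any() or (self.starts < 0).any():
            raise ConsistencyError(f"{self.contig}:{self.strand}: negative counts")
        bad = np.nonzero(self.starts > self.depth)[0]
        if bad.size:
            raise ConsistencyError(
                f"{self.contig}:{self.strand}: starts > depth at position {int(bad[0])}"
            )

    def __len__(self) -> int:
        return int(self.depth.size)


@dataclass
class Library:
    """A sequencing library: tracks keyed by (contig, strand) plus its size.

    ``library_size`` is the total number of mapped reads and is the
    denominator of every reads-per-million (RPM) normalisation.  When it
    is not supplied it defaults to the total number of read 5' ends in
    the tracks.
    """

    role: str
    tracks: Dict[Tuple[str, str], BaseTrack] = field(default_factory=dict)
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.library_size is None:
            self.library_size = int(
                sum(int(t.starts.sum()) for t in self.tracks.values())
            )
        if self.library_size <= 0:
            raise ValueError(f"library {self.role!r}: library_size must be positive")

    def track(self, contig: str, strand: str) -> BaseTrack | None:
        return self.tracks.get((contig, strand))

    def contigs(self) -> set:
        return {c for c, _ in self.tracks}

    def depth(self, contig: str, strand: str) -> np.ndarray:
        t = self.track(contig, strand)
        if t is None:
            raise KeyError(f"no track for {contig}:{strand} in {self.role}")
        return t.depth

    def starts(self, contig: str, strand: str) -> np.ndarray:
        t = self.track(contig, strand)
        if t is None:
            raise KeyError(f"no track for {contig}:{strand} in {self.role}")
        return t.starts


@dataclass
class LibrarySet:
    """Role-keyed collection of the libraries of one condition."""

    condition: str
    libraries: Dict[str, Library] = field(default_factory=dict)

    def __getitem__(self, role: str) -> Library:
        try:
            return self.libraries[role]
        except KeyError:
            raise KeyError(
                f"condition {self.condition!r} is missing library role {role!r}"
            ) from None

    def __contains__(self, role: str) -> bool:
        return role in self.libraries

    def require(self, roles: Iterable[str]) -> None:
        missing = [r for r in roles if r not in self.libraries]
        if missing:
            raise KeyError(
                f"condition {self.condition!r} is missing library role(s) "
                + ", ".join(missing)
            )


def count_starts(lib: Library, contig: str, strand: str, start: int, end: int) -> int:
    """Number of read 5' ends of ``lib`` falling in [start, end)."""
    t = lib.track(contig, strand)
    if t is None:
        return 0
    start = max(0, start)
    end = min(len(t), end)
    if end <= start:
        return 0
    return int(t.starts[start:end].sum())


def rpm(count: float, library_size: int) -> float:
    """Reads-per-million normalisation."""
    return 1e6 * count / library_size


def tracks_equal(a: Mapping[Tuple[str, str], BaseTrack],
                 b: Mapping[Tuple[str, str], BaseTrack]) -> bool:
    """Exact equality of two track collections (used by round-trip tests)."""
    if set(a) != set(b):
        return False
    for key in a:
        ta, tb = a[key], b[key]
        if len(ta) != len(tb):
            return False
        if not (np.array_equal(ta.depth, tb.depth)
                and np.array_equal(ta.starts, tb.starts)):
            return False
    return True
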
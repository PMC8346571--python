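"""Readers and writers for the on-disk formats the pipeline touches.

bedGraph pairs (depth + read-start tracks, one pair per strand per
library), samtools text mpileup, FASTA, and BED6+ output of peaks and
single-base sites.  All coordinates are 0-based half-open internally and
in BED; the mpileup reader converts from its 1-based positions at the
boundary.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .tracks import BaseTrack, ConsistencyError, Library


class FormatError(ValueError):
    """Malformed input file."""


class MpileupError(FormatError):
    """Malformed samtools mpileup line (carries the line number)."""


# ---------------------------------------------------------------------------
# bedGraph

def _read_bedgraph(path, contig_sizes: Mapping[str, int] | None) -> Dict[str, np.ndarray]:
    rows: List[Tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    arrays: Dict[str, np.ndarray] = {}
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "value"])
    contigs = set(df["contig"]) | (set(contig_sizes) if contig_sizes else set())
    for contig in contigs:
        sub = df[df["contig"] == contig].sort_values(["start", "end"])
        if contig_sizes and contig in contig_sizes:
            size = int(contig_sizes[contig])
        else:
            size = int(sub["end"].max()) if len(sub) else 0
        arr = np.zeros(size, dtype=np.int64)
        prev_end, prev_val = -1, None
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            if start < 0 or end > size or start >= end:
                raise FormatError(
                    f"{path}: bad interval {contig}:{start}-{end} (contig size {size})"
                )
            if value != int(value) or value < 0:
                raise FormatError(
                    f"{path}: non-count value {value} at {contig}:{start}-{end}"
                )
            if start < prev_end and value != prev_val:
                raise FormatError(
                    f"{path}: overlapping intervals with conflicting values at "
                    f"{contig}:{start}"
                )
            arr[start:end] = int(value)
            prev_end, prev_val = max(prev_end, end), value
        arrays[contig] = arr
    return arrays


def read_bedgraph_pair(
    depth_path,
    starts_path,
    strand: str,
    library_size: int | None = None,
    contig_sizes: Mapping[str, int] | None = None,
) -> Dict[str, BaseTrack]:
    """Read a (depth, starts) bedGraph pair into dense per-contig tracks.

    Uncovered positions are zero.  ``starts[i] > depth[i]`` anywhere is a
    consistency error naming the position, never silently clamped.
    Returns a dict keyed by contig; assemble a :class:`Library` from both
    strands with :func:`library_from_bedgraphs`.
    """
    depth = _read_bedgraph(depth_path, contig_sizes)
    starts = _read_bedgraph(starts_path, contig_sizes)
    tracks: Dict[str, BaseTrack] = {}
    for contig in sorted(set(depth) | set(starts)):
        d = depth.get(contig)
        s = starts.get(contig)
        if d is None:
            d = np.zeros_like(s)
        if s is None:
            s = np.zeros_like(d)
        if d.size != s.size:
            n = max(d.size, s.size)
            d = np.pad(d, (0, n - d.size))
            s = np.pad(s, (0, n - s.size))
        tracks[contig] = BaseTrack(contig, strand, d, s)  # validates starts<=depth
    return tracks


def library_from_bedgraphs(
    role: str,
    pairs: Mapping[str, Tuple[str, str]],
    library_size: int | None = None,
    contig_sizes: Mapping[str, int] | None = None,
) -> Library:
    """Build a Library from ``{strand: (depth_path, starts_path)}``."""
    tracks = {}
    for strand, (dpath, spath) in pairs.items():
        for contig, track in read_bedgraph_pair(
            dpath, spath, strand, contig_sizes=contig_sizes
        ).items():
            tracks[(contig, strand)] = track
    return Library(role=role, tracks=tracks, library_size=library_size)


def write_bedgraph(arr: np.ndarray, contig: str, path, mode: str = "w") -> None:
    """Run-length encode a dense per-position array as bedGraph."""
    with open(path, mode) as fh:
        if arr.size == 0:
            return
        change = np.nonzero(np.diff(arr))[0] + 1
        bounds = np.concatenate(([0], change, [arr.size]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            v = int(arr[a])
            if v != 0:
                fh.write(f"{contig}\t{int(a)}\t{int(b)}\t{v}\n")


def write_library_bedgraphs(lib: Library, outdir, prefix: str | None = None) -> Dict[str, Tuple[str, str]]:
    """Write one (depth, starts) bedGraph pair per strand; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    prefix = prefix or lib.role
    paths: Dict[str, Tuple[str, str]] = {}
    for strand, tag in (("+", "plus"), ("-", "minus")):
        dpath = os.path.join(outdir, f"{prefix}.{tag}.depth.bedgraph")
        spath = os.path.join(outdir, f"{prefix}.{tag}.starts.bedgraph")
        open(dpath, "w").close()
        open(spath, "w").close()
        for (contig, s), track in sorted(lib.tracks.items()):
            if s != strand:
                continue
            write_bedgraph(track.depth, contig, dpath, mode="a")
            write_bedgraph(track.starts, contig, spath, mode="a")
        paths[strand] = (dpath, spath)
    return paths


# ---------------------------------------------------------------------------
# samtools text mpileup

_BASE_CHARS = set(".,ACGTNacgtn*#<>")


def _scan_pileup_bases(bases: str, lineno: int) -> int:
    """Count read-start markers ('^') in an mpileup base column.

    '^' is followed by one mapping-quality character which is skipped
    unconditionally (it may itself look like a base or another marker).
    Indels ('+'/'-' followed by a length and that many characters), read
    ends ('$') and deletions/refskips are consumed but not counted.
    """
    starts = 0
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise MpileupError(f"line {lineno}: dangling '^' in base column")
            starts += 1
            i += 2  # marker + mapping quality
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise MpileupError(f"line {lineno}: indel without length")
            length = int(bases[i + 1 : j])
            if j + length > n:
                raise MpileupError(f"line {lineno}: truncated indel sequence")
            i = j + length
        elif c == "$":
            i += 1
        elif c in _BASE_CHARS:
            i += 1
        else:
            raise MpileupError(f"line {lineno}: unexpected character {c!r}")
    return starts


def read_mpileup(path, strand: str) -> Dict[str, BaseTrack]:
    """Read samtools text pileup into per-contig tracks.

    Depth is taken from column 4 and read-start counts from the '^'
    markers of the base column; the input is expected to come from a
    strand-split BAM, ``strand`` only labels the resulting tracks.
    """
    per_contig: Dict[str, Dict[int, Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise MpileupError(f"line {lineno}: expected >=5 pileup columns")
            contig, pos1, _ref, depth_s, bases = parts[:5]
            try:
                pos = int(pos1) - 1  # 1-based at this boundary only
                depth = int(depth_s)
            except ValueError:
                raise MpileupError(f"line {lineno}: non-integer position/depth") from None
            if pos < 0:
                raise MpileupError(f"line {lineno}: position must be >= 1")
            starts = _scan_pileup_bases(bases, lineno)
            per_contig.setdefault(contig, {})[pos] = (depth, starts)
    tracks: Dict[str, BaseTrack] = {}
    for contig, posmap in per_contig.items():
        size = max(posmap) + 1
        d = np.zeros(size, dtype=np.int64)
        s = np.zeros(size, dtype=np.int64)
        for pos, (dep, st) in posmap.items():
            d[pos], s[pos] = dep, st
        tracks[contig] = BaseTrack(contig, strand, d, s)
    return tracks


def write_mpileup(track: BaseTrack, path, ref: str | None = None, mode: str = "w") -> None:
    """Emit a minimal samtools-style pileup consistent with a track."""
    base = "." if track.strand == "+" else ","
    with open(path, mode) as fh:
        for pos in np.nonzero(track.depth)[0]:
            d = int(track.depth[pos])
            st = int(track.starts[pos])
            col = ("^]" + base) * st + base * (d - st)
            refbase = ref[pos] if ref is not None else "N"
            fh.write(f"{track.contig}\t{int(pos) + 1}\t{refbase}\t{d}\t{col}\t{'~' * d}\n")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    """Load a FASTA into contig->sequence strings (desk-scale genomes)."""
    seqs: Dict[str, List[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence before first header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


# ---------------------------------------------------------------------------
# BED6+ peaks and sites

_PEAK_COLS = [
    "contig", "start", "end", "name", "score", "strand",
    "summit", "fold", "p", "q", "peak_class", "ratio", "class_p", "class_q",
    "transcript_ids",
]

_SITE_COLS = [
    "contig", "start", "end", "name", "score", "strand",
    "m1", "m2", "srd", "starts_fto_minus", "motif", "peak_id", "gene_ids",
]


def _fmt(x) -> str:
    if isinstance(x, float):
        return repr(x)  # full precision so round trips are exact
    return str(x)


def write_peaks_bed(peaks: Sequence, path) -> None:
    """Write classified (or raw) peaks as BED6+ with a '#' header line."""
    from .peaks import Peak  # local import to avoid a cycle

    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_PEAK_COLS) + "\n")
        for p in peaks:
            tx = ",".join(p.transcript_ids) if p.transcript_ids else "."
            row = [
                p.contig, p.start, p.end, p.name, 0, p.strand,
                p.summit, p.fold, p.p, p.q,
                p.peak_class or ".", p.ratio, p.class_p, p.class_q, tx,
            ]
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def read_peaks_bed(path) -> list:
    from .peaks import Peak

    peaks = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            tx = tuple(f[14].split(",")) if f[14] != "." else ()
            peaks.append(
                Peak(
                    contig=f[0], start=int(f[1]), end=int(f[2]), name=f[3],
                    strand=f[5], summit=int(f[6]), fold=float(f[7]),
                    p=float(f[8]), q=float(f[9]),
                    peak_class="" if f[10] == "." else f[10],
                    ratio=float(f[11]), class_p=float(f[12]), class_q=float(f[13]),
                    transcript_ids=tx,
                )
            )
    return peaks


def write_sites_bed(sites: Sequence, path) -> None:
    """Write single-base m6Am site calls as 1-nt BED6+ intervals."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_SITE_COLS) + "\n")
        for s in sites:
            genes = ",".join(s.gene_ids) if s.gene_ids else "."
            row = [
                s.contig, s.position, s.position + 1, s.name, 0, s.strand,
                s.m1, s.m2, s.srd, s.starts_fto_minus, s.motif,
                s.peak_id or ".", genes,
            ]
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def read_sites_bed(path) -> list:
    from .srd import M6AmSite

    sites = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            genes = tuple(f[12].split(",")) if f[12] != "." else ()
            sites.append(
                M6AmSite(
                    contig=f[0], strand=f[5], position=int(f[1]), name=f[3],
                    m1=float(f[6]), m2=float(f[7]), srd=float(f[8]),
                    starts_fto_minus=int(f[9]), motif=f[10],
                    peak_id="" if f[11] == "." else f[11], gene_ids=genes,
                )
            )
    return sites
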
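"""IP-vs-input peak calling and the high-confidence 5'-UTR filter.

The caller scans fixed windows (default 50 nt, step 25) along every
contig/strand, tests the IP depth sum against its input expectation with
a one-sided Poisson test, corrects per strand with Benjamini-Hochberg,
and merges runs of windows that pass both the fold and the q cutoffs.
This is a deterministic, auditable reimplementation of a MeRIP-style
enrichment scan; parity with exomePeak/MACS2 is explicitly not claimed.

Fold enrichment is computed on counts-per-million with a small CPM
pseudocount, which makes folds exactly invariant to rescaling any one
library's counts together with its size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import TranscriptModel, five_prime_region
from .tracks import Library, count_starts, rpm


@dataclass
class PeakParams:
    window: int = 50
    step: int = 25
    min_fold: float = 3.0          # FOLD_ENRICHMENT cutoff for seed windows
    q_cutoff: float = 0.01
    # two-threshold (broad) calling: windows passing the seed cutoffs
    # nucleate a peak, which then extends over flanking windows passing
    # this laxer fold cutoff.  The extension is fold-gated only, so peak
    # intervals are invariant to rescaling a library's counts and size.
    boundary_fold: float = 1.5
    boundary_q: float = 1.0
    pseudocount_cpm: float = 1.0   # added to both CPM values before the fold
    pseudocount_reads: float = 1.0  # added to the input window count in the test
    frag_len: int = 150            # depth units per read: depth sums are
    # divided by this so the Poisson test runs on read-scale counts


@dataclass
class Peak:
    contig: str
    strand: str
    start: int
    end: int
    summit: int
    fold: float
    p: float
    q: float
    name: str = ""
    transcript_ids: Tuple[str, ...] = ()
    utr5_assigned: bool = False
    peak_class: str = ""           # "", "M6AM", "UTR5_M6A", "AMBIGUOUS"
    ratio: float = float("nan")
    class_p: float = float("nan")
    class_q: float = float("nan")

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start >= end")
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"peak {self.name}: summit outside interval")

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.contig == other.contig
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def window_fold(ip_count: float, input_count: float, ip_size: int, input_size: int,
                pseudocount_cpm: float = 1.0) -> float:
    """CPM-based fold enrichment with pseudocount."""
    ip_cpm = 1e6 * ip_count / ip_size
    in_cpm = 1e6 * input_count / input_size
    return (ip_cpm + pseudocount_cpm) / (in_cpm + pseudocount_cpm)


def _windows(length: int, window: int, step: int) -> np.ndarray:
    if length <= window:
        return np.array([0], dtype=np.int64)
    return np.arange(0, length - window + 1, step, dtype=np.int64)


def call_peaks(ip: Library, control: Library, params: PeakParams | None = None) -> List[Peak]:
    """Call IP-enriched peaks against the input library.

    Returns maximal merged runs of significant windows; each emitted
    peak has fold >= ``min_fold`` (fold of its best member window),
    q <= ``q_cutoff`` (minimum over member windows) and its summit at
    the leftmost position of maximum IP depth.  Output is sorted by
    (contig, start, strand).
    """
    params = params or PeakParams()
    if params.window < 1 or params.step < 1:
        raise ValueError("window and step must be >= 1")
    if not control.library_size or control.library_size <= 0:
        raise ValueError("zero input library size")

    # Collect per-window statistics, grouped by strand for BH correction.
    recs: Dict[str, List[Tuple[str, int, int, float, float]]] = {"+": [], "-": []}
    keys = sorted(set(ip.tracks) | set(control.tracks))
    for contig, strand in keys:
        ip_tr = ip.track(contig, strand)
        in_tr = control.track(contig, strand)
        n = max(len(ip_tr) if ip_tr else 0, len(in_tr) if in_tr else 0)
        if n == 0:
            continue
        ip_d = np.zeros(n)
        in_d = np.zeros(n)
        if ip_tr is not None:
            ip_d[: len(ip_tr)] = ip_tr.depth
        if in_tr is not None:
            in_d[: len(in_tr)] = in_tr.depth
        w = min(params.window, n)
        starts = _windows(n, w, params.step)
        ip_cs = np.concatenate(([0.0], np.cumsum(ip_d)))
        in_cs = np.concatenate(([0.0], np.cumsum(in_d)))
        ip_w = (ip_cs[starts + w] - ip_cs[starts]) / params.frag_len
        in_w = (in_cs[starts + w] - in_cs[starts]) / params.frag_len
        lam = (in_w + params.pseudocount_reads) * (ip.library_size / control.library_size)
        pvals = stats.poisson.sf(ip_w - 1, lam)
        folds = (1e6 * ip_w / ip.library_size + params.pseudocount_cpm) / (
            1e6 * in_w / control.library_size + params.pseudocount_cpm
        )
        for s0, f, p in zip(starts, folds, pvals):
            recs[strand].append((contig, int(s0), int(s0) + w, float(f), float(p)))

    peaks: List[Peak] = []
    b_fold = min(params.boundary_fold, params.min_fold)
    b_q = max(params.boundary_q, params.q_cutoff)
    for strand, rows in recs.items():
        if not rows:
            continue
        pvals = np.array([r[4] for r in rows])
        qvals = multipletests(pvals, method="fdr_bh")[1]
        ext = [
            (r[0], r[1], r[2], r[3], r[4], float(q),
             r[3] >= params.min_fold and q <= params.q_cutoff)
            for r, q in zip(rows, qvals)
            if r[3] >= b_fold and q <= b_q
        ]
        # maximal runs of chained boundary windows containing >=1 seed
        # window; peak statistics come from the seed windows
        by_contig: Dict[str, list] = {}
        for rec in ext:
            by_contig.setdefault(rec[0], []).append(rec)
        for contig, group in by_contig.items():
            group.sort(key=lambda r: (r[1], r[2]))
            runs: List[list] = []
            cur: List[tuple] = []
            for rec in group:
                if cur and rec[1] > max(r[2] for r in cur):
                    runs.append(cur)
                    cur = []
                cur.append(rec)
            if cur:
                runs.append(cur)
            merged = []
            for run in runs:
                seeds = [r for r in run if r[6]]
                if not seeds:
                    continue
                merged.append(
                    (contig, min(r[1] for r in run), max(r[2] for r in run),
                     max(r[3] for r in seeds), min(r[4] for r in seeds),
                     min(r[5] for r in seeds))
                )
            for _, s0, e0, fold, p, q in merged:
                ip_tr = ip.track(contig, strand)
                if ip_tr is not None and len(ip_tr) > s0:
                    seg = ip_tr.depth[s0 : min(e0, len(ip_tr))]
                    summit = s0 + int(np.argmax(seg))  # leftmost maximum
                else:
                    summit = s0
                peaks.append(
                    Peak(contig=contig, strand=strand, start=s0, end=e0,
                         summit=summit, fold=fold, p=p, q=q)
                )
    peaks.sort(key=lambda pk: (pk.contig, pk.start, pk.strand))
    for i, pk in enumerate(peaks, 1):
        pk.name = f"peak_{i}"
    return peaks


def filter_high_confidence(m6a_ip_peaks: Sequence[Peak], m7g_ip_peaks: Sequence[Peak]) -> List[Peak]:
    """High-confidence filter for the m6A-IP peak set.

    Keeps exactly those m6A-IP peaks that (1) overlap a same-strand
    cap-m7G-IP peak by >=1 bp and (2) have fold enrichment greater than
    the best-overlapping m7G-IP peak's.
    """
    out: List[Peak] = []
    for pk in m6a_ip_peaks:
        overlapping = [q for q in m7g_ip_peaks if pk.overlaps(q)]
        if not overlapping:
            continue
        best = max(q.fold for q in overlapping)
        if pk.fold > best:
            out.append(pk)
    return out


def assign_utr5(peaks: Sequence[Peak], genes: Sequence[TranscriptModel],
                margin: int = 100) -> List[Peak]:
    """Label peaks with the transcripts whose 5' region they overlap.

    The 5' region of a transcript is its 5'-UTR extended ``margin`` nt
    upstream of the annotated TSS (annotated TSSs and true cap sites do
    not always coincide).  Peaks overlapping no 5' region are flagged
    unassigned, not dropped.
    """
    by_key: Dict[Tuple[str, str], List[TranscriptModel]] = {}
    for g in genes:
        by_key.setdefault((g.contig, g.strand), []).append(g)
    out: List[Peak] = []
    for pk in peaks:
        hits = []
        for g in by_key.get((pk.contig, pk.strand), []):
            for s, e in five_prime_region(g, margin):
                if pk.start < e and s < pk.end:
                    hits.append(g.transcript_id)
                    break
        out.append(replace(pk, transcript_ids=tuple(sorted(set(hits))),
                           utr5_assigned=bool(hits)))
    return out


def peak_rpm(pk: Peak, lib: Library) -> float:
    """RPM of read 5' ends of ``lib`` within the peak interval."""
    return rpm(count_starts(lib, pk.contig, pk.strand, pk.start, pk.end),
               lib.library_size)
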
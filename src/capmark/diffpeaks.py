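"""Cross-condition peak comparison: stress induction and PCIF1 dependence.

Both analyses reuse the single-condition count machinery: peak read
counts (5'-end counts in the FTO(-) m6A-IP library of each condition)
enter a two-sided Fisher exact test against the library remainders, and
the intensity ratio is computed on RPM with a CPM pseudocount.  Peaks
from the two conditions are first harmonised by merging same-strand
overlapping intervals so a peak absent in one condition is still
testable over the merged interval.

Thresholds follow the respective definitions: a stress-responsive peak
needs ratio > 2 (or < 1/2) with BH q < 0.01; a PCIF1-dependent peak
needs WT/KO ratio > 2 with raw P < 0.05.  All inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import ClassifyParams, _ratio
from .peaks import Peak
from .tracks import LibrarySet, ROLE_FTO_MINUS, count_starts


@dataclass
class DiffPeakParams:
    ratio_cutoff: float = 2.0
    q_cutoff: float = 0.01       # stress mode (BH-corrected)
    p_cutoff: float = 0.05       # PCIF1 mode (raw P)
    pseudocount_cpm: float = 1.0


@dataclass
class ConditionDiff:
    peak_id: str
    contig: str
    strand: str
    start: int
    end: int
    peak_class: str
    rpm_a: float                 # stressed / WT condition
    rpm_b: float                 # untreated / KO condition
    ratio: float                 # a over b
    p: float
    q: float
    direction: str               # up / down / unchanged (stress mode)
    dependent: bool = False      # PCIF1 mode


def merge_condition_peaks(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]) -> List[Peak]:
    """Union of two peak sets with >=1-bp same-strand overlaps merged.

    The merged peak keeps the class label of its members when they agree
    (first non-empty label otherwise) and the best fold/q among members.
    """
    by_key: Dict[Tuple[str, str], List[Peak]] = {}
    for pk in list(peaks_a) + list(peaks_b):
        by_key.setdefault((pk.contig, pk.strand), []).append(pk)
    merged: List[Peak] = []
    for (contig, strand), group in sorted(by_key.items()):
        group.sort(key=lambda p: (p.start, p.end))
        cur: List[Peak] = []
        def flush() -> None:
            if not cur:
                return
            start = min(p.start for p in cur)
            end = max(p.end for p in cur)
            classes = [p.peak_class for p in cur if p.peak_class]
            merged.append(
                Peak(
                    contig=contig, strand=strand, start=start, end=end,
                    summit=max(cur, key=lambda p: p.fold).summit,
                    fold=max(p.fold for p in cur),
                    p=min(p.p for p in cur), q=min(p.q for p in cur),
                    peak_class=classes[0] if classes else "",
                    transcript_ids=tuple(
                        sorted({t for p in cur for t in p.transcript_ids})
                    ),
                )
            )
        for pk in group:
            if cur and pk.start < max(p.end for p in cur):
                cur.append(pk)
            else:
                flush()
                cur = [pk]
        flush()
    merged.sort(key=lambda p: (p.contig, p.start, p.strand))
    for i, pk in enumerate(merged, 1):
        pk.name = f"mpeak_{i}"
    return merged


def _condition_counts(pk: Peak, libs: LibrarySet) -> Tuple[int, int]:
    libs.require([ROLE_FTO_MINUS])
    lib = libs[ROLE_FTO_MINUS]
    return count_starts(lib, pk.contig, pk.strand, pk.start, pk.end), lib.library_size


def _test_peaks(peaks: Sequence[Peak], libs_a: LibrarySet, libs_b: LibrarySet,
                params: DiffPeakParams) -> List[ConditionDiff]:
    cparams = ClassifyParams(pseudocount_cpm=params.pseudocount_cpm)
    rows: List[ConditionDiff] = []
    pvals = []
    for pk in peaks:
        ca, size_a = _condition_counts(pk, libs_a)
        cb, size_b = _condition_counts(pk, libs_b)
        _, p = stats.fisher_exact(
            [[ca, size_a - ca], [cb, size_b - cb]], alternative="two-sided"
        )
        pvals.append(float(p))
        rows.append(
            ConditionDiff(
                peak_id=pk.name, contig=pk.contig, strand=pk.strand,
                start=pk.start, end=pk.end, peak_class=pk.peak_class,
                rpm_a=1e6 * ca / size_a, rpm_b=1e6 * cb / size_b,
                ratio=_ratio(ca, cb, size_a, size_b, cparams),
                p=float(p), q=float("nan"), direction="unchanged",
            )
        )
    if rows:
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(rows, qvals):
            r.q = float(q)
    return rows


def stress_diff(peaks: Sequence[Peak], untreated: LibrarySet, stressed: LibrarySet,
                params: DiffPeakParams | None = None) -> List[ConditionDiff]:
    """Stress-responsive peaks: |fold| > 2 between stressed and untreated.

    ``peaks`` should be the harmonised union (see
    :func:`merge_condition_peaks`).  direction is "up" when
    ratio(stress/untreated) > cutoff with q < q_cutoff, "down" for the
    mirror case, else "unchanged".
    """
    params = params or DiffPeakParams()
    rows = _test_peaks(peaks, stressed, untreated, params)
    for r in rows:
        if r.ratio > params.ratio_cutoff and r.q < params.q_cutoff:
            r.direction = "up"
        elif r.ratio < 1.0 / params.ratio_cutoff and r.q < params.q_cutoff:
            r.direction = "down"
        else:
            r.direction = "unchanged"
    return rows


def pcif1_dependence(peaks: Sequence[Peak], wt: LibrarySet, ko: LibrarySet,
                     params: DiffPeakParams | None = None) -> List[ConditionDiff]:
    """PCIF1-dependent peaks: WT/KO ratio > 2 with raw P < 0.05 (strict)."""
    params = params or DiffPeakParams()
    rows = _test_peaks(peaks, wt, ko, params)
    for r in rows:
        r.dependent = r.ratio > params.ratio_cutoff and r.p < params.p_cutoff
        r.direction = "up" if r.dependent else "unchanged"
    return rows
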
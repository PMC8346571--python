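"""Start-rate-difference (SRD) scoring and single-base m6Am site calling.

For a position i inside a demethylase-sensitive (m6Am) peak,

    m1 = [FTO(-) start reads at i] / [FTO(-) depth at i]
    m2 = ([FTO(-) depth at i] - [FTO(+) depth at i]) / [FTO(-) depth at i]
    SRD = m1 + m2

m1 captures the read-start pile-up expected at the first transcribed
nucleotide; m2 captures demethylase sensitivity of the coverage (the
FTO(+) start rate is too noisy to use directly, so coverage is used).
By default the depths entering m2 are library-size normalised (RPM);
raw-count mode is available behind a flag.

A position is called m6Am when five criteria hold: (1) it lies inside an
m6Am peak and carries an adenosine; (2) its FTO(-) start reads are >= 20;
(3) its FTO(-) start rate exceeds the cap-m7G-IP start rate; (4) the
m7G-IP start coverage exceeds the input's (RPM); (5) it is among the top
3 SRD scores of the peak with SRD > 1 (ties at rank 3 all included).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .peaks import Peak
from .tracks import (
    Library,
    LibrarySet,
    ROLE_FTO_MINUS,
    ROLE_FTO_PLUS,
    ROLE_INPUT,
    ROLE_M7G,
)

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


@dataclass(frozen=True)
class SRDComponents:
    position: int
    m1: float
    m2: float

    @property
    def srd(self) -> float:
        return self.m1 + self.m2


@dataclass
class SiteParams:
    min_starts: int = 20        # criterion 2
    min_srd: float = 1.0        # criterion 5 score floor
    top: int = 3                # criterion 5 rank cutoff (per peak)
    require_base_a: bool = True  # criterion 1 base identity
    normalized: bool = True      # RPM-normalise depths in m2 and counts in (4)


@dataclass
class M6AmSite:
    contig: str
    strand: str
    position: int
    m1: float
    m2: float
    srd: float
    starts_fto_minus: int
    motif: str = "undefined"     # BCA / non-BCA / undefined
    peak_id: str = ""
    gene_ids: Tuple[str, ...] = ()
    name: str = ""
    criteria: Tuple[bool, bool, bool, bool, bool] = (True,) * 5


def srd_score(pos: int, fto_minus: Library, fto_plus: Library, contig: str,
              strand: str, normalized: bool = True) -> SRDComponents | None:
    """SRD components at one position; None where FTO(-) depth is zero."""
    d_minus = fto_minus.depth(contig, strand)
    s_minus = fto_minus.starts(contig, strand)
    t_plus = fto_plus.track(contig, strand)
    dm = float(d_minus[pos]) if pos < d_minus.size else 0.0
    if dm <= 0:
        return None
    dp = float(t_plus.depth[pos]) if t_plus is not None and pos < len(t_plus) else 0.0
    if normalized:
        dm_n = dm / fto_minus.library_size
        dp_n = dp / fto_plus.library_size
    else:
        dm_n, dp_n = dm, dp
    m1 = float(s_minus[pos]) / dm
    m2 = (dm_n - dp_n) / dm_n
    return SRDComponents(position=pos, m1=m1, m2=m2)


def _sense_base(genome: Mapping[str, str], contig: str, pos: int, strand: str) -> str | None:
    seq = genome.get(contig) if hasattr(genome, "get") else genome[contig]
    if seq is None or pos < 0 or pos >= len(seq):
        return None
    base = seq[pos].upper().replace("U", "T")
    if strand == "-":
        base = base.translate(_COMPLEMENT)
    return base


def annotate_motif(genome: Mapping[str, str], contig: str, pos: int, strand: str) -> str:
    """Sequence context of a site: BCA, non-BCA, or undefined.

    BCA means base(-1) = C and base(-2) in {C, U/T, G}, read 5'->3' on
    the sense strand with the modified A at position 0.  Fewer than two
    upstream bases -> undefined.
    """
    if strand == "+":
        up1, up2 = pos - 1, pos - 2
    else:
        up1, up2 = pos + 1, pos + 2
    b1 = _sense_base(genome, contig, up1, strand)
    b2 = _sense_base(genome, contig, up2, strand)
    if b1 is None or b2 is None:
        return "undefined"
    return "BCA" if (b1 == "C" and b2 in {"C", "G", "T"}) else "non-BCA"


def call_m6am_sites(peak: Peak, libs: LibrarySet, genome: Mapping[str, str],
                    params: SiteParams | None = None) -> List[M6AmSite]:
    """Evaluate the five site criteria at every position of one m6Am peak.

    The top-3 SRD rank (criterion 5) is computed over all positions of
    the peak with defined SRD, independent of the other criteria, so the
    result does not depend on evaluation order.
    """
    params = params or SiteParams()
    libs.require([ROLE_INPUT, ROLE_M7G, ROLE_FTO_MINUS, ROLE_FTO_PLUS])
    minus, plus = libs[ROLE_FTO_MINUS], libs[ROLE_FTO_PLUS]
    m7g, inp = libs[ROLE_M7G], libs[ROLE_INPUT]
    contig, strand = peak.contig, peak.strand

    def arr(lib: Library, which: str) -> np.ndarray:
        t = lib.track(contig, strand)
        out = np.zeros(peak.end - peak.start, dtype=float)
        if t is None:
            return out
        lo, hi = peak.start, min(peak.end, len(t))
        if hi > lo:
            src = t.depth if which == "d" else t.starts
            out[: hi - lo] = src[lo:hi]
        return out

    d_minus, s_minus = arr(minus, "d"), arr(minus, "s")
    d_plus = arr(plus, "d")
    d_m7g, s_m7g = arr(m7g, "d"), arr(m7g, "s")
    s_inp = arr(inp, "s")

    defined = d_minus > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = np.where(defined, s_minus / d_minus, np.nan)
        if params.normalized:
            dm_n = d_minus / minus.library_size
            dp_n = d_plus / plus.library_size
        else:
            dm_n, dp_n = d_minus, d_plus
        m2 = np.where(defined, (dm_n - dp_n) / np.where(defined, dm_n, 1.0), np.nan)
        srd = m1 + m2
        rate_m7g = np.where(d_m7g > 0, s_m7g / np.where(d_m7g > 0, d_m7g, 1.0), 0.0)

    if params.normalized:
        cov_m7g = s_m7g / m7g.library_size
        cov_inp = s_inp / inp.library_size
    else:
        cov_m7g, cov_inp = s_m7g, s_inp

    positions = np.arange(peak.start, peak.end)
    if params.require_base_a:
        bases = np.array(
            [_sense_base(genome, contig, int(p), strand) or "N" for p in positions]
        )
        c1 = bases == "A"
    else:
        c1 = np.ones_like(defined)
    c2 = s_minus >= params.min_starts
    c3 = defined & (m1 > rate_m7g)
    c4 = cov_m7g > cov_inp
    # criterion 5: top-`top` SRD scores of the peak, ties at the rank
    # boundary included, plus the absolute SRD floor
    srd_def = srd[defined]
    if srd_def.size:
        order = np.sort(srd_def)[::-1]
        thresh = order[min(params.top, order.size) - 1]
        c5 = defined & (srd >= thresh) & (srd > params.min_srd)
    else:
        c5 = np.zeros_like(defined)

    keep = defined & c1 & c2 & c3 & c4 & c5
    sites: List[M6AmSite] = []
    for idx in np.nonzero(keep)[0]:
        pos = int(positions[idx])
        sites.append(
            M6AmSite(
                contig=contig, strand=strand, position=pos,
                m1=float(m1[idx]), m2=float(m2[idx]), srd=float(srd[idx]),
                starts_fto_minus=int(s_minus[idx]),
                motif=annotate_motif(genome, contig, pos, strand),
                peak_id=peak.name, gene_ids=tuple(peak.transcript_ids),
                criteria=(bool(c1[idx]), bool(c2[idx]), bool(c3[idx]),
                          bool(c4[idx]), bool(c5[idx])),
            )
        )
    for i, s in enumerate(sites, 1):
        s.name = f"{peak.name or 'peak'}_site_{i}"
    return sites


def call_all_sites(peaks: Sequence[Peak], libs: LibrarySet,
                   genome: Mapping[str, str],
                   params: SiteParams | None = None) -> List[M6AmSite]:
    """Site calling over every peak classified M6AM."""
    sites: List[M6AmSite] = []
    for pk in peaks:
        if pk.peak_class == "M6AM":
            sites.extend(call_m6am_sites(pk, libs, genome, params))
    for i, s in enumerate(sites, 1):
        s.name = f"site_{i}"
    return sites


def tss_concordance(sites: Sequence[M6AmSite],
                    tss: Sequence[Tuple[str, int, str]]) -> pd.DataFrame:
    """Signed distance from each site to its nearest TSS.

    ``tss`` holds (contig, position, strand) triples (e.g. CAGE CTSS or
    annotation).  Distances are in transcript orientation: positive
    means the site lies downstream of the TSS.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS set")
    by_key: Dict[Tuple[str, str], np.ndarray] = {}
    for contig, pos, strand in tss:
        by_key.setdefault((contig, strand), []).append(pos)  # type: ignore[arg-type]
    by_key = {k: np.sort(np.asarray(v)) for k, v in by_key.items()}
    rows = []
    for s in sites:
        cand = by_key.get((s.contig, s.strand))
        if cand is None or cand.size == 0:
            rows.append((s.name, s.contig, s.position, s.strand, np.nan))
            continue
        raw = s.position - cand if s.strand == "+" else cand - s.position
        d = raw[np.argmin(np.abs(raw))]
        rows.append((s.name, s.contig, s.position, s.strand, int(d)))
    return pd.DataFrame(rows, columns=["site", "contig", "position", "strand", "distance"])
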
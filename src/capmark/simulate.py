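"""Synthetic benchmark generator with planted m6Am / 5'-UTR m6A truth.

The generator emulates the causal structure of the four-library design:
fragments of ~150 nt; the cap-m7G IP enriches cap-retaining 5' fragments
(whose 5' ends sit exactly at the TSS, up to a small end-repair jitter);
the m6A-IP enriches fragments carrying a methylated base on top of the
cap enrichment carried over from the serial IP; FTO(+) treatment removes
the configured fraction of m6Am (default 0.95) and leaves internal m6A
untouched; counts are Poisson.  Planted m6Am always sits at an
A-starting TSS, optionally in a BCA context written into the genomic
sequence; planted m6A sits inside the annotated 5'-UTR in a GGACH
context, close enough to the TSS that its peak overlaps the cap-fragment
coverage (as real 5'-UTR m6A peaks do).

A low rate of uniform genomic background fragments and the start jitter
give every TSS a little non-cap coverage; without them the start-rate
comparison against the m7G-IP library degenerates to exact ties.

The ground truth is consumed only by tests and evaluation, never by the
pipeline.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .annotation import TranscriptModel
from .tracks import (
    ALL_ROLES,
    BaseTrack,
    Library,
    LibrarySet,
    ROLE_FTO_MINUS,
    ROLE_FTO_PLUS,
    ROLE_INPUT,
    ROLE_M7G,
)

_FLANK = 300          # upstream genomic flank per transcript slot
_TAIL_GAP = 400
_MAX_LEN = 4000


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Defaults are the benchmark conditions: 500 transcripts, 70% with
    m6Am at an A-starting TSS, 100x mean coverage, 150/30 nt fragments,
    10x antibody enrichment, 0.95 FTO demethylation efficiency for m6Am
    and none for m6A, 66% BCA context at m6Am TSSs.
    """

    n_transcripts: int = 500
    length_mean: int = 3200
    length_sd: int = 500
    length_min: int = 1800
    frac_m6am: float = 0.7
    frac_m6a: float = 0.2
    coverage: float = 100.0
    fragment_mean: int = 150
    fragment_sd: int = 30
    ip_enrichment: float = 10.0       # m6A antibody, per methylated fragment
    m7g_enrichment: float = 3.0       # cap antibody, per cap fragment
    fto_efficiency: float = 0.95      # fraction of m6Am removed by FTO(+)
    fto_m6a_effect: float = 0.0       # fraction of internal m6A affected
    start_jitter: float = 0.02        # cap 5' ends shifted +-1 nt
    background_frac: float = 0.05     # uniform genomic background fragments
    # minor unmethylated alternative TSSs upstream of the main one: real
    # promoters are heterogeneous, and the m6A-IP purifies the methylated
    # major-TSS caps away from this halo while the m7G-IP keeps it
    alt_tss_frac: float = 0.05
    alt_tss_min: int = 10
    alt_tss_max: int = 60
    bca_prob: float = 0.66
    minus_strand_frac: float = 0.5
    # placement band of internal m6A within the 5'-UTR (nt from the TSS):
    # clear of the dense cap coverage yet overlapping the m7G-IP peak
    m6a_min_pos: int = 150
    m6a_max_pos: int = 190
    transcripts_per_contig: int = 25
    stress_frac: float = 0.3          # of m6Am transcripts, in stress pairs
    stress_fold: float = 4.0
    library_size_factors: Dict[str, float] = field(
        default_factory=lambda: {
            ROLE_INPUT: 1.0, ROLE_M7G: 0.9, ROLE_FTO_MINUS: 1.1, ROLE_FTO_PLUS: 0.8,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        fracs = [
            self.frac_m6am, self.frac_m6a, self.fto_efficiency,
            self.fto_m6a_effect, self.start_jitter, self.background_frac,
            self.bca_prob, self.minus_strand_frac, self.stress_frac,
        ]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.frac_m6am + self.frac_m6a > 1.0 + 1e-9:
            raise ValueError("frac_m6am + frac_m6a must not exceed 1")
        if self.n_transcripts < 0 or self.coverage <= 0:
            raise ValueError("need n_transcripts >= 0 and coverage > 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class _Design:
    """Shared transcript layout of one benchmark (condition independent)."""

    config: SimConfig
    contig_len: int
    n_contigs: int
    g0: np.ndarray            # genomic start per transcript
    length: np.ndarray
    strand: np.ndarray        # '+'/'-'
    contig_idx: np.ndarray
    status: np.ndarray        # 'm6am' / 'm6a' / 'none'
    utr_len: np.ndarray
    m6a_pos: np.ndarray       # transcript coordinate, -1 if none
    alt_tss: np.ndarray       # upstream offset of the minor alternative TSS
    bca: np.ndarray           # bool, only meaningful for m6am
    stress_induced: np.ndarray
    sequences: Dict[str, str]

    def contig_name(self, idx: int) -> str:
        return f"chrS{idx + 1:02d}"

    def tss_genomic(self, i: int) -> int:
        if self.strand[i] == "+":
            return int(self.g0[i])
        return int(self.g0[i] + self.length[i] - 1)

    def to_genomic(self, i: int, t: int) -> int:
        if self.strand[i] == "+":
            return int(self.g0[i] + t)
        return int(self.g0[i] + self.length[i] - 1 - t)


@dataclass
class SimResult:
    libraries: LibrarySet
    genes: List[TranscriptModel]
    truth: pd.DataFrame
    sequences: Dict[str, str]
    config: SimConfig


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G in ASCII


def _set_sense_base(seq: bytearray, pos: int, strand: str, base: str) -> None:
    b = ord(base)
    seq[pos] = b if strand == "+" else _COMP[b]


def _make_design(config: SimConfig, rng: np.random.Generator) -> _Design:
    n = config.n_transcripts
    per = max(1, config.transcripts_per_contig)
    slot = _FLANK + _MAX_LEN + _TAIL_GAP
    n_contigs = int(np.ceil(n / per)) if n else 0
    contig_len = per * slot

    length = np.clip(
        np.round(rng.normal(config.length_mean, config.length_sd, n)),
        config.length_min, _MAX_LEN,
    ).astype(np.int64)
    contig_idx = np.arange(n) // per
    g0 = (np.arange(n) % per) * slot + _FLANK + contig_idx * contig_len
    strand = np.where(rng.random(n) < config.minus_strand_frac, "-", "+")
    u = rng.random(n)
    status = np.where(
        u < config.frac_m6am, "m6am",
        np.where(u < config.frac_m6am + config.frac_m6a, "m6a", "none"),
    )
    utr_len = rng.integers(280, 451, n)
    m6a_pos = np.full(n, -1, dtype=np.int64)
    for i in np.nonzero(status == "m6a")[0]:
        p = int(rng.integers(config.m6a_min_pos, config.m6a_max_pos + 1))
        m6a_pos[i] = p
        utr_len[i] = int(rng.integers(max(280, p + 110), 481))
    alt_tss = rng.integers(config.alt_tss_min, config.alt_tss_max + 1, n)
    bca = rng.random(n) < config.bca_prob
    is_am = status == "m6am"
    stress = np.zeros(n, dtype=bool)
    stress[is_am] = rng.random(int(is_am.sum())) < config.stress_frac

    # genomic sequence with forced contexts
    sequences: Dict[str, str] = {}
    arrs: List[bytearray] = []
    for c in range(n_contigs):
        codes = rng.integers(0, 4, contig_len)
        arrs.append(bytearray(_BASES[codes].tobytes()))
    for i in range(n):
        c = int(contig_idx[i])
        seq = arrs[c]
        off = c * contig_len
        st = str(strand[i])
        tss_local = (
            int(g0[i] - off) if st == "+" else int(g0[i] + length[i] - 1 - off)
        )
        up = -1 if st == "+" else 1  # genomic step towards sense-upstream
        if status[i] == "m6am":
            _set_sense_base(seq, tss_local, st, "A")
            if bca[i]:
                _set_sense_base(seq, tss_local + up, st, "C")
                _set_sense_base(seq, tss_local + 2 * up, st,
                                "CGT"[int(rng.integers(0, 3))])
            else:
                _set_sense_base(seq, tss_local + up, st,
                                "AGT"[int(rng.integers(0, 3))])
        elif status[i] == "m6a":
            # GGACH with the methylated A third (sense orientation)
            p_local = (
                int(g0[i] + m6a_pos[i] - off)
                if st == "+"
                else int(g0[i] + length[i] - 1 - m6a_pos[i] - off)
            )
            down = -up
            for k, b in ((2 * up, "G"), (up, "G"), (0, "A"), (down, "C")):
                _set_sense_base(seq, p_local + k, st, b)
            _set_sense_base(seq, p_local + 2 * down, st,
                            "ACT"[int(rng.integers(0, 3))])
    for c in range(n_contigs):
        sequences[f"chrS{c + 1:02d}"] = arrs[c].decode()

    return _Design(
        config=config, contig_len=contig_len, n_contigs=n_contigs,
        g0=g0, length=length, strand=strand, contig_idx=contig_idx,
        status=status, utr_len=utr_len, m6a_pos=m6a_pos, alt_tss=alt_tss,
        bca=bca, stress_induced=stress, sequences=sequences,
    )


def _design_genes(design: _Design) -> List[TranscriptModel]:
    models = []
    for i in range(design.config.n_transcripts):
        g0, L = int(design.g0[i]), int(design.length[i])
        c = design.contig_name(int(design.contig_idx[i]))
        off = int(design.contig_idx[i]) * design.contig_len
        lo, hi = g0 - off, g0 - off + L
        st = str(design.strand[i])
        ul = int(design.utr_len[i])
        if st == "+":
            tss, cds_start = lo, lo + ul
            utr5 = ((lo, lo + ul),)
        else:
            tss, cds_start = hi - 1, hi - 1 - ul
            utr5 = ((hi - ul, hi),)
        models.append(
            TranscriptModel(
                transcript_id=f"tx{i + 1:04d}", gene_id=f"gene{i + 1:04d}",
                contig=c, strand=st, tss=tss, cds_start=cds_start,
                exons=((lo, hi),), utr5=utr5, coding=True,
            )
        )
    return models


def _design_truth(design: _Design) -> pd.DataFrame:
    rows = []
    for i in range(design.config.n_transcripts):
        c = design.contig_name(int(design.contig_idx[i]))
        off = int(design.contig_idx[i]) * design.contig_len
        tss = design.tss_genomic(i) - off
        if design.m6a_pos[i] >= 0:
            a = design.to_genomic(i, int(design.m6a_pos[i]) - 100) - off
            b = design.to_genomic(i, int(design.m6a_pos[i]) + 100) - off
            m6a_start, m6a_end = min(a, b), max(a, b) + 1
        else:
            m6a_start = m6a_end = -1
        rows.append(
            (
                f"tx{i + 1:04d}", c, str(design.strand[i]), tss,
                str(design.status[i]), int(design.m6a_pos[i]),
                m6a_start, m6a_end,
                bool(design.bca[i]) if design.status[i] == "m6am" else None,
                bool(design.stress_induced[i]),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "contig", "strand", "tss", "status",
            "m6a_tx_pos", "m6a_start", "m6a_end", "bca", "stress_induced",
        ],
    )


def _cap_weight(cfg: SimConfig, role: str, methylated: np.ndarray,
                stress_mult: np.ndarray) -> np.ndarray:
    """Per-transcript weight of the cap-retaining fragment class."""
    if role == ROLE_INPUT:
        return np.ones_like(stress_mult)
    if role == ROLE_M7G:
        return np.full_like(stress_mult, cfg.m7g_enrichment)
    e_ip = np.where(methylated, cfg.ip_enrichment * stress_mult, 1.0)
    if role == ROLE_FTO_PLUS:
        # FTO removes m6Am with the configured efficiency
        e_ip = np.where(
            methylated,
            (1.0 - cfg.fto_efficiency) * cfg.ip_enrichment * stress_mult
            + cfg.fto_efficiency * 1.0,
            1.0,
        )
    return cfg.m7g_enrichment * e_ip


def _m6a_weight(cfg: SimConfig, role: str) -> float:
    if role == ROLE_INPUT:
        return 1.0
    if role == ROLE_M7G:
        return 1.0
    if role == ROLE_FTO_MINUS:
        return cfg.ip_enrichment
    return (1.0 - cfg.fto_m6a_effect) * cfg.ip_enrichment + cfg.fto_m6a_effect


def _sample_library(design: _Design, role: str, rng: np.random.Generator,
                    pcif1_ko: bool = False, stressed: bool = False) -> Library:
    cfg = design.config
    n = cfg.n_transcripts
    G = design.n_contigs * design.contig_len
    flen = cfg.fragment_mean

    plus_starts = np.zeros(G, dtype=np.int64)
    minus_starts = np.zeros(G, dtype=np.int64)
    plus_diff = np.zeros(G + 1, dtype=np.int64)
    minus_diff = np.zeros(G + 1, dtype=np.int64)
    total = 0

    if n:
        L = design.length.astype(float)
        methylated = (design.status == "m6am") & (not pcif1_ko)
        stress_mult = np.where(
            stressed & design.stress_induced, cfg.stress_fold, 1.0
        )
        has_m6a = design.status == "m6a"

        cap_base = np.full(n, cfg.coverage * (1.0 - cfg.alt_tss_frac))
        alt_base = np.full(n, cfg.coverage * cfg.alt_tss_frac)
        m6a_base = np.where(has_m6a, cfg.coverage, 0.0)
        int_base = np.maximum(
            cfg.coverage * L / flen - cap_base - alt_base - m6a_base, 0.0
        )

        cap_mass = cap_base * _cap_weight(cfg, role, methylated, stress_mult)
        # minor alternative-TSS caps are never m6Am methylated
        alt_mass = alt_base * _cap_weight(
            cfg, role, np.zeros(n, dtype=bool), stress_mult
        )
        m6a_mass = m6a_base * _m6a_weight(cfg, role)
        int_mass = int_base  # background fragments of the transcript, weight 1

        n_target = cfg.library_size_factors.get(role, 1.0) * cfg.coverage * L.sum() / flen
        tx_mass = cap_mass + alt_mass + m6a_mass + int_mass
        scale = (1.0 - cfg.background_frac) * n_target / tx_mass.sum()

        def draw_lengths(k: int) -> np.ndarray:
            return np.clip(
                np.round(rng.normal(cfg.fragment_mean, cfg.fragment_sd, k)),
                50, 2 * cfg.fragment_mean + 50,
            ).astype(np.int64)

        def accumulate(tx: np.ndarray, s: np.ndarray, lens: np.ndarray) -> None:
            nonlocal total
            total += tx.size
            g0 = design.g0[tx]
            Lt = design.length[tx]
            lens = np.minimum(lens, np.maximum(Lt - s, 1))
            minus = design.strand[tx] == "-"
            g5 = np.where(minus, g0 + Lt - 1 - s, g0 + s)
            a = np.where(minus, g5 - lens + 1, g5)
            b = np.where(minus, g5 + 1, g5 + lens)
            clo = (g5 // design.contig_len) * design.contig_len
            chi = clo + design.contig_len
            a = np.clip(a, clo, chi)
            b = np.clip(b, clo, chi)
            for m, st_arr, df_arr in (
                (~minus, plus_starts, plus_diff), (minus, minus_starts, minus_diff),
            ):
                if m.any():
                    st_arr += np.bincount(g5[m], minlength=G)
                    df_arr += np.bincount(a[m], minlength=G + 1)
                    df_arr -= np.bincount(b[m], minlength=G + 1)

        def cap_positions(tx: np.ndarray, offset: np.ndarray) -> np.ndarray:
            # 5' ends of capped fragments sit at the TSS; a small fraction is
            # nibbled 1-2 nt downstream.  No upstream shifts: the RNA has no
            # nucleotides before its first transcribed base.
            s = offset.astype(np.int64).copy()
            jit = rng.random(tx.size) < cfg.start_jitter
            k = int(jit.sum())
            if k:
                s[jit] += np.where(rng.random(k) < 0.5, 1, 2)
            return s

        # cap-retaining fragments: 5' end at the TSS (with end-repair jitter)
        n_cap = rng.poisson(cap_mass * scale)
        tx = np.repeat(np.arange(n), n_cap)
        if tx.size:
            accumulate(tx, cap_positions(tx, np.zeros(tx.size)),
                       draw_lengths(tx.size))

        # minor alternative-TSS caps, a few tens of nt upstream, unmethylated
        n_alt = rng.poisson(alt_mass * scale)
        tx = np.repeat(np.arange(n), n_alt)
        if tx.size:
            accumulate(tx, cap_positions(tx, -design.alt_tss[tx]),
                       draw_lengths(tx.size))

        # fragments overlapping the internal m6A site
        n_m6a = rng.poisson(m6a_mass * scale)
        tx = np.repeat(np.arange(n), n_m6a)
        if tx.size:
            lens = draw_lengths(tx.size)
            p = design.m6a_pos[tx]
            u = (rng.random(tx.size) * np.minimum(lens, p + 1)).astype(np.int64)
            accumulate(tx, p - u, lens)

        # uniformly positioned transcript fragments; on transcripts with an
        # internal m6A these avoid the site window (site-overlapping
        # fragments carry the mark and belong to the class above)
        n_int = rng.poisson(int_mass * scale)
        tx = np.repeat(np.arange(n), n_int)
        if tx.size:
            lens = draw_lengths(tx.size)
            Lt = design.length[tx]
            p = design.m6a_pos[tx]
            w_lo = np.where(p >= 0, np.maximum(p - lens + 1, 0), 0)
            w_len = np.where(p >= 0, p - w_lo + 1, 0)
            v = (rng.random(tx.size) * np.maximum(Lt - w_len, 1)).astype(np.int64)
            s = np.where((p >= 0) & (v >= w_lo), v + w_len, v)
            accumulate(tx, s, lens)

        # genomic background fragments, both strands
        n_bg = rng.poisson(cfg.background_frac * n_target)
        if n_bg:
            total += int(n_bg)
            g5 = rng.integers(0, G, n_bg)
            lens = draw_lengths(n_bg)
            minus = rng.random(n_bg) < 0.5
            clo = (g5 // design.contig_len) * design.contig_len
            chi = clo + design.contig_len
            a = np.clip(np.where(minus, g5 - lens + 1, g5), clo, chi)
            b = np.clip(np.where(minus, g5 + 1, g5 + lens), clo, chi)
            for m, st_arr, df_arr in (
                (~minus, plus_starts, plus_diff), (minus, minus_starts, minus_diff),
            ):
                if m.any():
                    st_arr += np.bincount(g5[m], minlength=G)
                    df_arr += np.bincount(a[m], minlength=G + 1)
                    df_arr -= np.bincount(b[m], minlength=G + 1)

    plus_depth = np.cumsum(plus_diff)[:G]
    minus_depth = np.cumsum(minus_diff)[:G]
    tracks: Dict[Tuple[str, str], BaseTrack] = {}
    for c in range(design.n_contigs):
        name = design.contig_name(c)
        lo, hi = c * design.contig_len, (c + 1) * design.contig_len
        tracks[(name, "+")] = BaseTrack(name, "+", plus_depth[lo:hi], plus_starts[lo:hi])
        tracks[(name, "-")] = BaseTrack(name, "-", minus_depth[lo:hi], minus_starts[lo:hi])
    return Library(role=role, tracks=tracks, library_size=max(total, 1))


def _sample_libraries(design: _Design, rng: np.random.Generator, condition: str,
                      pcif1_ko: bool = False, stressed: bool = False) -> LibrarySet:
    libs = {
        role: _sample_library(design, role, rng, pcif1_ko=pcif1_ko, stressed=stressed)
        for role in ALL_ROLES
    }
    return LibrarySet(condition=condition, libraries=libs)


def simulate(config: SimConfig) -> SimResult:
    """Generate one condition's four libraries plus annotation and truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = _make_design(config, rng)
    libs = _sample_libraries(design, rng, condition="untreated")
    return SimResult(
        libraries=libs, genes=_design_genes(design), truth=_design_truth(design),
        sequences=design.sequences, config=config,
    )


def simulate_pair(config: SimConfig, kind: str) -> Tuple[SimResult, SimResult]:
    """Two conditions over one shared transcript design.

    kind = "null" (independent resampling, no effect), "stress"
    (condition B has the flagged m6Am peaks induced ``stress_fold``-fold)
    or "pcif1_ko" (condition B lacks all m6Am).  Returned as (A, B) =
    (untreated/WT, stressed/KO); truth describes condition A.
    """
    if kind not in ("null", "stress", "pcif1_ko"):
        raise ValueError(f"unknown pair kind {kind!r}")
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = _make_design(config, rng)
    genes, truth = _design_genes(design), _design_truth(design)
    libs_a = _sample_libraries(design, rng, condition="untreated")
    libs_b = _sample_libraries(
        design, rng,
        condition={"null": "replicate", "stress": "stressed", "pcif1_ko": "pcif1_ko"}[kind],
        pcif1_ko=(kind == "pcif1_ko"), stressed=(kind == "stress"),
    )
    a = SimResult(libs_a, genes, truth, design.sequences, config)
    b = SimResult(libs_b, genes, truth, design.sequences, config)
    return a, b


# ---------------------------------------------------------------------------
# evaluation against the planted truth

def evaluate_calls(truth: pd.DataFrame, peaks: Sequence, sites: Sequence) -> pd.DataFrame:
    """Precision/recall/F1 of peak classes and exact-base site calls.

    A called m6Am peak is correct when it covers a planted m6Am TSS on
    its strand; a called 5'-UTR m6A peak when it overlaps a planted m6A
    interval.  Sites must match the planted TSS at the exact base.
    Undefined ratios are reported as NaN ("NA").
    """
    am_truth = truth[truth["status"] == "m6am"]
    m6a_truth = truth[truth["status"] == "m6a"]
    am_keys = set(zip(am_truth["contig"], am_truth["strand"], am_truth["tss"]))

    def covers_tss(pk) -> bool:
        return any(
            c == pk.contig and s == pk.strand and pk.start <= t < pk.end
            for c, s, t in am_keys
        )

    def hits_m6a(pk) -> bool:
        sub = m6a_truth[
            (m6a_truth["contig"] == pk.contig) & (m6a_truth["strand"] == pk.strand)
        ]
        return bool(
            ((sub["m6a_start"] < pk.end) & (pk.start < sub["m6a_end"])).any()
        )

    called_am = [pk for pk in peaks if pk.peak_class == "M6AM"]
    called_m6a = [pk for pk in peaks if pk.peak_class == "UTR5_M6A"]

    def prf(tp_called: int, n_called: int, tp_truth: int, n_truth: int):
        prec = tp_called / n_called if n_called else float("nan")
        rec = tp_truth / n_truth if n_truth else float("nan")
        f1 = (
            2 * prec * rec / (prec + rec)
            if n_called and n_truth and (prec + rec) > 0
            else float("nan")
        )
        return prec, rec, f1

    rows = []
    tp_am_calls = sum(covers_tss(pk) for pk in called_am)
    rec_am = sum(
        any(
            pk.contig == c and pk.strand == s and pk.start <= t < pk.end
            for pk in called_am
        )
        for c, s, t in am_keys
    )
    rows.append(("m6am_peaks", *prf(tp_am_calls, len(called_am), rec_am, len(am_keys)),
                 len(am_keys), len(called_am)))

    tp_m6a_calls = sum(hits_m6a(pk) for pk in called_m6a)
    rec_m6a = 0
    for _, r in m6a_truth.iterrows():
        if any(
            pk.contig == r["contig"] and pk.strand == r["strand"]
            and pk.start < r["m6a_end"] and r["m6a_start"] < pk.end
            for pk in called_m6a
        ):
            rec_m6a += 1
    rows.append(("utr5_m6a_peaks", *prf(tp_m6a_calls, len(called_m6a), rec_m6a,
                                        len(m6a_truth)), len(m6a_truth), len(called_m6a)))

    site_keys = {(s.contig, s.strand, s.position) for s in sites}
    tp_sites = len(site_keys & am_keys)
    rows.append(("sites", *prf(tp_sites, len(site_keys), tp_sites, len(am_keys)),
                 len(am_keys), len(site_keys)))
    return pd.DataFrame(
        rows, columns=["target", "precision", "recall", "f1", "n_true", "n_called"]
    )
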
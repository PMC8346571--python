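"""Window-scan peak caller vs exhaustive oracle; high-confidence filter."""

import numpy as np
import pytest
from scipy import stats

import capmark as cm
from capmark.peaks import (
    Peak,
    PeakParams,
    assign_utr5,
    call_peaks,
    filter_high_confidence,
)
from capmark.annotation import TranscriptModel
from conftest import make_library


# --- independent exhaustive oracle ----------------------------------------

def _bh(pvals):
    """Benjamini-Hochberg, written out step by step."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def oracle_call_peaks(ip, control, params):
    """Per-window brute force mirroring the documented peak definition."""
    rows = {"+": [], "-": []}
    for contig, strand in sorted(set(ip.tracks) | set(control.tracks)):
        ip_tr, in_tr = ip.track(contig, strand), control.track(contig, strand)
        n = max(len(ip_tr) if ip_tr else 0, len(in_tr) if in_tr else 0)
        ip_d = np.zeros(n)
        in_d = np.zeros(n)
        if ip_tr is not None:
            ip_d[: len(ip_tr)] = ip_tr.depth
        if in_tr is not None:
            in_d[: len(in_tr)] = in_tr.depth
        w = min(params.window, n)
        starts = [0] if n <= w else list(range(0, n - w + 1, params.step))
        for s0 in starts:
            ipw = ip_d[s0 : s0 + w].sum() / params.frag_len
            inw = in_d[s0 : s0 + w].sum() / params.frag_len
            lam = (inw + params.pseudocount_reads) * ip.library_size / control.library_size
            p = stats.poisson.sf(ipw - 1, lam)
            fold = (1e6 * ipw / ip.library_size + params.pseudocount_cpm) / (
                1e6 * inw / control.library_size + params.pseudocount_cpm
            )
            rows[strand].append([contig, s0, s0 + w, fold, p])
    out = []
    for strand, recs in rows.items():
        if not recs:
            continue
        q = _bh([r[4] for r in recs])
        b_fold = min(params.boundary_fold, params.min_fold)
        b_q = max(params.boundary_q, params.q_cutoff)
        ext = [
            r + [qi, r[3] >= params.min_fold and qi <= params.q_cutoff]
            for r, qi in zip(recs, q)
            if r[3] >= b_fold and qi <= b_q
        ]
        by_contig = {}
        for r in ext:
            by_contig.setdefault(r[0], []).append(r)
        for contig, group in by_contig.items():
            group.sort(key=lambda r: (r[1], r[2]))
            run = []
            runs = []
            for r in group:
                if run and r[1] > max(x[2] for x in run):
                    runs.append(run)
                    run = []
                run.append(r)
            if run:
                runs.append(run)
            for run in runs:
                seeds = [r for r in run if r[6]]
                if not seeds:
                    continue
                s0 = min(r[1] for r in run)
                e0 = max(r[2] for r in run)
                ip_tr = ip.track(contig, strand)
                seg = ip_tr.depth[s0:e0] if ip_tr is not None else np.zeros(1)
                out.append({
                    "contig": contig, "strand": strand, "start": s0, "end": e0,
                    "fold": max(r[3] for r in seeds),
                    "p": min(r[4] for r in seeds),
                    "q": min(r[5] for r in seeds),
                    "summit": s0 + int(np.argmax(seg)),
                })
    out.sort(key=lambda d: (d["contig"], d["start"], d["strand"]))
    return out


def _random_pair(rng, n=2000, contigs=("cA", "cB")):
    ip_tracks, in_tracks = {}, {}
    for contig in contigs:
        for strand in "+-":
            base = rng.integers(5, 30)
            ip_d = rng.poisson(base, n)
            in_d = rng.poisson(base, n)
            for _ in range(rng.integers(0, 4)):  # planted enriched blocks
                s0 = int(rng.integers(0, n - 300))
                width = int(rng.integers(60, 300))
                ip_d[s0 : s0 + width] += rng.poisson(base * rng.integers(2, 8), width)
            ip_s = rng.binomial(ip_d, 0.1)
            in_s = rng.binomial(in_d, 0.1)
            ip_tracks[(contig, strand)] = cm.BaseTrack(contig, strand, ip_d, ip_s)
            in_tracks[(contig, strand)] = cm.BaseTrack(contig, strand, in_d, in_s)
    ip = cm.Library("ip", ip_tracks, library_size=1_000_000)
    control = cm.Library("input", in_tracks, library_size=1_200_000)
    return ip, control


class TestCallPeaks:
    def test_uniform_equal_coverage_yields_no_peaks(self):
        ip = make_library("ip", "c", "+", [50] * 2000, [0] * 2000, 10000)
        control = make_library("in", "c", "+", [50] * 2000, [0] * 2000, 10000)
        assert call_peaks(ip, control) == []

    def test_all_zero_ip_yields_no_peaks(self):
        ip = make_library("ip", "c", "+", [0] * 2000, [0] * 2000, 10000)
        control = make_library("in", "c", "+", [20] * 2000, [0] * 2000, 10000)
        assert call_peaks(ip, control) == []

    def test_zero_input_library_size_is_an_error(self):
        ip = make_library("ip", "c", "+", [1] * 100, [0] * 100, 10)
        control = make_library("in", "c", "+", [1] * 100, [0] * 100, 10)
        control.library_size = 0
        with pytest.raises(ValueError, match="library size"):
            call_peaks(ip, control)

    def test_single_enriched_block_matches_oracle(self):
        depth = np.full(2000, 20)
        depth[500:700] = 300
        ip = make_library("ip", "c", "+", depth, np.zeros(2000, int), 100_000)
        control = make_library("in", "c", "+", np.full(2000, 20),
                               np.zeros(2000, int), 100_000)
        params = PeakParams()
        peaks = call_peaks(ip, control, params)
        expected = oracle_call_peaks(ip, control, params)
        assert len(peaks) == len(expected) == 1
        pk, ex = peaks[0], expected[0]
        assert (pk.start, pk.end, pk.summit) == (ex["start"], ex["end"], ex["summit"])
        assert pk.fold == pytest.approx(ex["fold"])
        assert pk.q == pytest.approx(ex["q"])
        assert 450 <= pk.start <= 500 and 700 <= pk.end <= 750

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_tracks_match_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ip, control = _random_pair(rng)
        params = PeakParams()
        peaks = call_peaks(ip, control, params)
        expected = oracle_call_peaks(ip, control, params)
        assert len(peaks) == len(expected)
        for pk, ex in zip(peaks, expected):
            assert (pk.contig, pk.strand, pk.start, pk.end, pk.summit) == (
                ex["contig"], ex["strand"], ex["start"], ex["end"], ex["summit"])
            assert pk.fold == pytest.approx(ex["fold"])
            assert pk.p == pytest.approx(ex["p"], abs=1e-12)
            assert pk.q == pytest.approx(ex["q"], abs=1e-12)

    def test_emitted_peaks_respect_min_fold_and_q(self):
        rng = np.random.default_rng(5)
        ip, control = _random_pair(rng)
        params = PeakParams()
        for pk in call_peaks(ip, control, params):
            assert pk.fold >= params.min_fold
            assert pk.q <= params.q_cutoff

    def test_raising_min_fold_never_adds_peaks(self):
        rng = np.random.default_rng(6)
        ip, control = _random_pair(rng)
        loose = {(p.contig, p.strand, p.start, p.end)
                 for p in call_peaks(ip, control, PeakParams(min_fold=3.0))}
        for fold in (4.0, 6.0, 10.0):
            strict = {(p.contig, p.strand, p.start, p.end)
                      for p in call_peaks(ip, control, PeakParams(min_fold=fold))}
            # a stricter seed threshold can shrink or split runs, never
            # create enrichment elsewhere
            for contig, strand, s0, e0 in strict:
                assert any(c == contig and st == strand and s0 >= a and e0 <= b
                           for c, st, a, b in loose)

    def test_scaling_one_library_leaves_folds_and_peaks_unchanged(self):
        rng = np.random.default_rng(7)
        ip, control = _random_pair(rng, n=1500, contigs=("cA",))
        base = call_peaks(ip, control)
        for c in (3, 10):
            scaled_tracks = {
                key: cm.BaseTrack(t.contig, t.strand, t.depth * c, t.starts * c)
                for key, t in ip.tracks.items()
            }
            scaled = cm.Library("ip", scaled_tracks, library_size=ip.library_size * c)
            got = call_peaks(scaled, control)
            assert [(p.start, p.end) for p in got] == [(p.start, p.end) for p in base]
            for a, b in zip(got, base):
                assert a.fold == pytest.approx(b.fold)

    def test_summit_tie_broken_leftmost(self):
        depth = np.full(600, 10)
        depth[200:300] = 500  # flat plateau
        ip = make_library("ip", "c", "+", depth, np.zeros(600, int), 50_000)
        control = make_library("in", "c", "+", np.full(600, 10),
                               np.zeros(600, int), 50_000)
        (pk,) = call_peaks(ip, control)
        assert pk.summit == 200


def _mk_peak(contig, strand, start, end, fold, name=""):
    return Peak(contig=contig, strand=strand, start=start, end=end,
                summit=start, fold=fold, p=1e-9, q=1e-8, name=name)


class TestHighConfidenceFilter:
    def test_empty_m7g_list_filters_everything(self):
        peaks = [_mk_peak("c", "+", 0, 100, 5.0)]
        assert filter_high_confidence(peaks, []) == []

    def test_overlap_with_lower_m7g_fold_retained(self):
        m6a = [_mk_peak("c", "+", 0, 100, 5.0)]
        m7g = [_mk_peak("c", "+", 50, 150, 3.0)]
        assert filter_high_confidence(m6a, m7g) == m6a

    def test_equal_or_higher_m7g_fold_rejected(self):
        m6a = [_mk_peak("c", "+", 0, 100, 3.0)]
        m7g = [_mk_peak("c", "+", 50, 150, 3.0)]
        assert filter_high_confidence(m6a, m7g) == []

    def test_opposite_strand_overlap_does_not_count(self):
        m6a = [_mk_peak("c", "+", 0, 100, 5.0)]
        m7g = [_mk_peak("c", "-", 0, 100, 1.0)]
        assert filter_high_confidence(m6a, m7g) == []

    def test_random_sets_match_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        def random_peaks(k):
            out = []
            for i in range(k):
                s0 = int(rng.integers(0, 3000))
                out.append(_mk_peak(
                    str(rng.choice(["c1", "c2"])), str(rng.choice(["+", "-"])),
                    s0, s0 + int(rng.integers(10, 400)),
                    float(rng.uniform(1, 10)), name=f"p{i}"))
            return out
        for _ in range(10):
            m6a, m7g = random_peaks(15), random_peaks(15)
            got = {p.name for p in filter_high_confidence(m6a, m7g)}
            oracle = set()
            for p in m6a:  # quadratic brute force
                folds = [q.fold for q in m7g
                         if q.contig == p.contig and q.strand == p.strand
                         and p.start < q.end and q.start < p.end]
                if folds and p.fold > max(folds):
                    oracle.add(p.name)
            assert got == oracle


class TestAssignUtr5:
    def _gene(self, tid, contig, strand, tss, cds_start, exons, utr5):
        return TranscriptModel(transcript_id=tid, gene_id=tid, contig=contig,
                               strand=strand, tss=tss, cds_start=cds_start,
                               exons=exons, utr5=utr5)

    def test_overlapping_peak_assigned(self):
        g = self._gene("t1", "c", "+", 1000, 1300, ((1000, 2000),), ((1000, 1300),))
        (pk,) = assign_utr5([_mk_peak("c", "+", 990, 1120, 5.0)], [g], margin=0)
        assert pk.utr5_assigned and pk.transcript_ids == ("t1",)

    def test_peak_in_cds_unassigned(self):
        g = self._gene("t1", "c", "+", 1000, 1300, ((1000, 2000),), ((1000, 1300),))
        (pk,) = assign_utr5([_mk_peak("c", "+", 1600, 1900, 5.0)], [g], margin=0)
        assert not pk.utr5_assigned and pk.transcript_ids == ()

    def test_upstream_margin_applies_in_transcript_orientation(self):
        g = self._gene("t1", "c", "-", 1999, 1699, ((1000, 2000),), ((1700, 2000),))
        # 50 nt genomically downstream of the minus-strand TSS = upstream
        (pk,) = assign_utr5([_mk_peak("c", "-", 2010, 2060, 5.0)], [g], margin=100)
        assert pk.utr5_assigned
        (pk,) = assign_utr5([_mk_peak("c", "-", 2010, 2060, 5.0)], [g], margin=0)
        assert not pk.utr5_assigned

    def test_randomized_assignment_matches_base_overlap_oracle(self):
        rng = np.random.default_rng(9)
        genes = []
        for i in range(12):
            strand = str(rng.choice(["+", "-"]))
            g0 = int(rng.integers(0, 8000))
            L = int(rng.integers(500, 2000))
            ul = int(rng.integers(100, 400))
            if strand == "+":
                genes.append(self._gene(f"t{i}", "c", "+", g0, g0 + ul,
                                        ((g0, g0 + L),), ((g0, g0 + ul),)))
            else:
                genes.append(self._gene(f"t{i}", "c", "-", g0 + L - 1,
                                        g0 + L - 1 - ul,
                                        ((g0, g0 + L),), ((g0 + L - ul, g0 + L),)))
        margin = 100
        peaks = []
        for i in range(40):
            s0 = int(rng.integers(0, 9000))
            peaks.append(_mk_peak("c", str(rng.choice(["+", "-"])),
                                  s0, s0 + int(rng.integers(20, 400)), 5.0, f"p{i}"))
        got = assign_utr5(peaks, genes, margin=margin)
        for pk in got:
            expected = set()
            for g in genes:  # base-by-base oracle
                if g.strand != pk.strand:
                    continue
                bases = {b for s, e in g.utr5 for b in range(s, e)}
                if g.strand == "+":
                    bases |= set(range(max(0, g.tss - margin), g.tss))
                else:
                    bases |= set(range(g.tss + 1, g.tss + 1 + margin))
                if bases & set(range(pk.start, pk.end)):
                    expected.add(g.transcript_id)
            assert set(pk.transcript_ids) == expected
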
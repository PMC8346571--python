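"""Gene model: transcripts, TSSs and 5'-UTR intervals from GTF.

The transcription start site is the 5'-most transcribed position in
transcript orientation (on the minus strand, the interval end - 1 in
0-based coordinates).  The 5'-UTR is the union of exonic bases strictly
5' of the CDS start, again in transcript orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import gffutils

Interval = Tuple[int, int]  # 0-based half-open


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    tss: int
    cds_start: int | None          # genomic coordinate of the first CDS base
    exons: Tuple[Interval, ...]    # sorted genomic intervals
    utr5: Tuple[Interval, ...]     # exonic bases 5' of the CDS start
    coding: bool = True

    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def _to_half_open(feature) -> Interval:
    # gffutils keeps GTF's 1-based inclusive coordinates
    return (feature.start - 1, feature.end)


def _utr5_from_exons(exons: Sequence[Interval], strand: str, cds_start: int) -> Tuple[Interval, ...]:
    out: List[Interval] = []
    for s, e in exons:
        if strand == "+":
            a, b = s, min(e, cds_start)
        else:
            a, b = max(s, cds_start + 1), e
        if a < b:
            out.append((a, b))
    return tuple(sorted(out))


def load_gene_model(gtf_path) -> List[TranscriptModel]:
    """Parse a RefSeq-style GTF into per-transcript models.

    Transcripts without exons are skipped with a warning; transcripts
    without CDS are flagged non-coding and their whole exonic extent is
    treated as a potential 5' region.
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: List[TranscriptModel] = []
    for tr in db.features_of_type(("transcript", "mRNA")):
        exons = sorted(_to_half_open(e) for e in db.children(tr, featuretype="exon"))
        if not exons:
            warnings.warn(f"transcript {tr.id} has no exons; skipped")
            continue
        cds = sorted(_to_half_open(c) for c in db.children(tr, featuretype="CDS"))
        strand = tr.strand
        tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
        if cds:
            cds_start = cds[0][0] if strand == "+" else cds[-1][1] - 1
            utr5 = _utr5_from_exons(exons, strand, cds_start)
            coding = True
        else:
            cds_start = None
            utr5 = tuple(exons)
            coding = False
        models.append(
            TranscriptModel(
                transcript_id=tr.id,
                gene_id=tr.attributes.get("gene_id", [tr.id])[0],
                contig=tr.seqid,
                strand=strand,
                tss=tss,
                cds_start=cds_start,
                exons=tuple(exons),
                utr5=utr5,
                coding=coding,
            )
        )
    return models


def write_gtf(models: Sequence[TranscriptModel], path) -> None:
    """Emit transcript/exon/CDS GTF lines (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            lo = min(s for s, _ in m.exons)
            hi = max(e for _, e in m.exons)
            fh.write(
                f"{m.contig}\tcapmark\ttranscript\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.contig}\tcapmark\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.coding and m.cds_start is not None:
                # CDS = exonic bases from the CDS start to the transcript 3' end
                for s, e in m.exons:
                    if m.strand == "+":
                        a, b = max(s, m.cds_start), e
                    else:
                        a, b = s, min(e, m.cds_start + 1)
                    if a < b:
                        fh.write(
                            f"{m.contig}\tcapmark\tCDS\t{a + 1}\t{b}\t.\t{m.strand}\t0\t{attrs}\n"
                        )


def five_prime_region(model: TranscriptModel, margin: int) -> List[Interval]:
    """5'-UTR intervals extended ``margin`` nt upstream of the TSS."""
    region = list(model.utr5)
    if margin > 0:
        if model.strand == "+":
            region.append((max(0, model.tss - margin), model.tss))
        else:
            region.append((model.tss + 1, model.tss + 1 + margin))
    return region
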
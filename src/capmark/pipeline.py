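"""End-to-end orchestration: peaks -> classification -> single-base sites.

The stages mirror the experimental logic: call enriched peaks in the
FTO(-) m6A-IP sample against input, call cap-m7G-IP peaks the same way,
keep the high-confidence intersection (overlap + higher fold in the
m6A-IP), restrict to 5' regions of annotated transcripts, classify each
peak by demethylase sensitivity, and finally call single-base m6Am sites
inside the demethylase-sensitive peaks with the SRD criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import yaml

from .annotation import TranscriptModel
from .classify import ClassifyParams, DiffResult, classify_peaks
from .peaks import Peak, PeakParams, assign_utr5, call_peaks, filter_high_confidence
from .srd import M6AmSite, SiteParams, call_all_sites
from .tracks import (
    LibrarySet,
    ROLE_FTO_MINUS,
    ROLE_FTO_PLUS,
    ROLE_INPUT,
    ROLE_M7G,
)


@dataclass
class PipelineParams:
    peaks: PeakParams = field(default_factory=PeakParams)
    # the cap antibody enriches its single cap fragment per transcript at a
    # lower per-region fold than the m6A antibody; its scan uses a laxer fold
    m7g_peaks: PeakParams = field(default_factory=lambda: PeakParams(min_fold=1.2))
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    sites: SiteParams = field(default_factory=SiteParams)
    utr5_margin: int = 100
    utr5_only: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            peaks=PeakParams(**data.get("peaks", {})),
            m7g_peaks=PeakParams(**data.get("m7g_peaks", {"min_fold": 1.2})),
            classify=ClassifyParams(**data.get("classify", {})),
            sites=SiteParams(**data.get("sites", {})),
            utr5_margin=data.get("utr5_margin", 100),
            utr5_only=data.get("utr5_only", True),
        )


@dataclass
class PipelineResult:
    m6a_ip_peaks: List[Peak]
    m7g_ip_peaks: List[Peak]
    high_confidence: List[Peak]
    classified: List[Peak]
    diffs: List[DiffResult]
    sites: List[M6AmSite]

    def peaks_of_class(self, cls: str) -> List[Peak]:
        return [p for p in self.classified if p.peak_class == cls]


def run_pipeline(libs: LibrarySet, genes: Sequence[TranscriptModel],
                 genome: Mapping[str, str],
                 params: PipelineParams | None = None) -> PipelineResult:
    params = params or PipelineParams()
    libs.require([ROLE_INPUT, ROLE_M7G, ROLE_FTO_MINUS, ROLE_FTO_PLUS])

    m6a_peaks = call_peaks(libs[ROLE_FTO_MINUS], libs[ROLE_INPUT], params.peaks)
    m7g_peaks = call_peaks(libs[ROLE_M7G], libs[ROLE_INPUT], params.m7g_peaks)
    hc = filter_high_confidence(m6a_peaks, m7g_peaks)
    hc = assign_utr5(hc, genes, margin=params.utr5_margin)
    if params.utr5_only:
        hc = [p for p in hc if p.utr5_assigned]
    diffs = classify_peaks(hc, libs[ROLE_FTO_MINUS], libs[ROLE_FTO_PLUS],
                           params.classify)
    sites = call_all_sites(hc, libs, genome, params.sites)
    return PipelineResult(
        m6a_ip_peaks=m6a_peaks, m7g_ip_peaks=m7g_peaks, high_confidence=hc,
        classified=hc, diffs=diffs, sites=sites,
    )
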
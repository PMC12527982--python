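"""Prophage HI_min computation and the SdP / SiP / SuP trichotomy.

A prophage stays repressed under LexA control only if LexA can bind an
operator in one of its promoter regions.  The decisive statistic is HI_min,
the minimum Heterology Index over all potential SOS boxes in the prophage's
promoter windows, compared against the host's genome-specific thresholds:

    HI_min <= HI_C1          -> SdP (SOS-dependent: LexA binding expected)
    HI_min >= HI_C2          -> SiP (SOS-independent: binding not expected)
    HI_C1 < HI_min < HI_C2   -> SuP (uncertain)

Both boundaries are inclusive because the thresholds are cluster extrema: a
value equal to max(low cluster) is itself a member of the low cluster.
A prophage whose promoters contain no PSB at all cannot be LexA-repressed
under this model and is called SiP with an explicit ``no_psb`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .genome_io import GenomeRecord, ProphageRegion, extract_promoters
from .host_profiling import STATUS_OK, HostProfile
from .sosbox_scoring import PsbHit, SosBoxMatrix, default_matrix, scan_region

SDP = "SdP"
SIP = "SiP"
SUP = "SuP"
NOT_AVAILABLE = "NA"


class ProfileNotOkError(ValueError):
    """Classification was requested against a host profile that is not OK."""

    def __init__(self, status: str):
        self.status = status
        super().__init__(f"host profile status is {status}, not {STATUS_OK}")


@dataclass
class ProphageCall:
    prophage_id: str
    replicon_id: str
    start: int
    end: int
    hi_min: float | None
    n_psbs: int
    class_label: str
    no_psb_flag: bool = False
    supporting_hits: list[PsbHit] = field(default_factory=list)
    host_status: str = STATUS_OK


@dataclass
class ClassSummary:
    n_sdp: int
    n_sip: int
    n_sup: int
    pct_sdp: float
    pct_sip: float
    pct_sup: float
    empty_flag: bool = False

    @property
    def total(self) -> int:
        return self.n_sdp + self.n_sip + self.n_sup


def prophage_hi_min(
    genome: GenomeRecord,
    region: ProphageRegion,
    matrix: SosBoxMatrix | None = None,
    upstream_len: int = 300,
    into_gene_len: int = 50,
    mismatch_allowance: int = 0,
) -> tuple[float | None, list[PsbHit]]:
    """Minimum HI over all PSBs in the prophage's promoter windows.

    Promoter windows are taken for every CDS overlapping the region;
    hits shared by overlapping windows are deduplicated by interval.
    Returns ``(None, [])`` when no window yields a PSB (or the region has no
    annotated CDS).
    """
    matrix = matrix or default_matrix()
    seen: dict[tuple[int, int], PsbHit] = {}
    for prom in extract_promoters(genome, region, upstream_len, into_gene_len):
        for hit in scan_region(
            matrix, genome, (prom.start, prom.end), mismatch_allowance
        ):
            seen.setdefault((hit.start, hit.end), hit)
    hits = [seen[k] for k in sorted(seen)]
    if not hits:
        return None, []
    return min(h.hi for h in hits), hits


def classify(hi_min: float | None, profile: HostProfile) -> tuple[str, bool]:
    """Apply the trichotomy; returns ``(label, no_psb_flag)``."""
    if profile.status != STATUS_OK:
        raise ProfileNotOkError(profile.status)
    if hi_min is None:
        return SIP, True
    if hi_min <= profile.hi_c1:
        return SDP, False
    if hi_min >= profile.hi_c2:
        return SIP, False
    return SUP, False


def call_prophages(
    genome: GenomeRecord,
    regions: Sequence[ProphageRegion],
    profile: HostProfile,
    matrix: SosBoxMatrix | None = None,
    upstream_len: int = 300,
    into_gene_len: int = 50,
    mismatch_allowance: int = 0,
) -> list[ProphageCall]:
    """One ProphageCall per region.

    On hosts whose profile is not OK the calls carry class ``NA`` and the
    host status, mirroring the exclusion of LexA-less or CSB-less genera.
    """
    matrix = matrix or default_matrix()
    calls = []
    for region in regions:
        hi_min, hits = prophage_hi_min(
            genome, region, matrix, upstream_len, into_gene_len,
            mismatch_allowance,
        )
        if profile.status != STATUS_OK:
            label, flag = NOT_AVAILABLE, hi_min is None
        else:
            label, flag = classify(hi_min, profile)
        calls.append(
            ProphageCall(
                prophage_id=region.prophage_id,
                replicon_id=region.replicon_id,
                start=region.start,
                end=region.end,
                hi_min=hi_min,
                n_psbs=len(hits),
                class_label=label,
                no_psb_flag=flag,
                supporting_hits=hits,
                host_status=profile.status,
            )
        )
    return calls


def _pct(count: int, total: int) -> float:
    """Percentage rounded to 2 decimals, half-up (display convention)."""
    if total == 0:
        return 0.0
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def summarize(calls: Sequence[ProphageCall]) -> ClassSummary:
    """Class counts and percentages over classified calls (``NA`` excluded)."""
    n_sdp = sum(1 for c in calls if c.class_label == SDP)
    n_sip = sum(1 for c in calls if c.class_label == SIP)
    n_sup = sum(1 for c in calls if c.class_label == SUP)
    return summarize_counts(n_sdp, n_sip, n_sup)


def summarize_counts(n_sdp: int, n_sip: int, n_sup: int) -> ClassSummary:
    total = n_sdp + n_sip + n_sup
    return ClassSummary(
        n_sdp=n_sdp,
        n_sip=n_sip,
        n_sup=n_sup,
        pct_sdp=_pct(n_sdp, total),
        pct_sip=_pct(n_sip, total),
        pct_sup=_pct(n_sup, total),
        empty_flag=total == 0,
    )
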
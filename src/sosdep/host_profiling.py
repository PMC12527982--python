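"""Host-side profiling: LexA detection, canonical SOS box, and HI thresholds.

A genome is usable for prophage classification only if it (1) encodes LexA,
(2) carries a canonical SOS box (CSB) upstream of *lexA* — evidence that LexA
autoregulates through the expected operator — and (3) yields enough potential
SOS boxes (PSBs) genome-wide for the HI distribution to be split into a
low-HI (binding) and a high-HI (non-binding) cluster.  The split gives two
genome-specific thresholds: HI_C1, the upper edge of the low cluster, and
HI_C2, the lower edge of the high cluster.  Thresholds are always derived per
genome; HI distributions differ significantly even between related species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import GenomeRecord, PromoterRegion, extract_promoters
from .sosbox_scoring import PsbHit, SosBoxMatrix, default_matrix, scan_region

STATUS_OK = "OK"
STATUS_NO_LEXA = "NO_LEXA"
STATUS_NO_CSB = "NO_CSB"
STATUS_AMBIGUOUS = "AMBIGUOUS_CLUSTERING"

DEFAULT_CSB_CUTOFF = 12.0
DEFAULT_MIN_PSB_COUNT = 10
#: Minimum local-alignment score per reference residue (BLOSUM62 half-bits)
#: for a CDS to be accepted as LexA.  The E. coli self-match scores ~5.3;
#: recognizable cross-genus LexA orthologs score well above 1.5.
DEFAULT_LEXA_SCORE_PER_LEN = 1.5


@dataclass(frozen=True)
class LexaLocus:
    feature_id: str
    start: int
    end: int
    strand: str
    detection_score: float
    detection_method: str = "similarity"


@dataclass(frozen=True)
class CsbEvidence:
    hit: PsbHit
    distance_to_lexa_start: int


@dataclass
class ThresholdResult:
    ok: bool
    hi_c1: float | None = None
    hi_c2: float | None = None
    low_cluster: list[float] = field(default_factory=list)
    high_cluster: list[float] = field(default_factory=list)
    reason: str | None = None


@dataclass
class HostProfile:
    genome_id: str
    status: str
    lexa: LexaLocus | None = None
    csb: CsbEvidence | None = None
    psb_his: list[float] = field(default_factory=list)
    psb_hits: list[PsbHit] = field(default_factory=list)
    hi_c1: float | None = None
    hi_c2: float | None = None
    low_cluster: list[float] = field(default_factory=list)
    high_cluster: list[float] = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        doc = {
            "genome_id": self.genome_id,
            "status": self.status,
            "lexa": None
            if self.lexa is None
            else {
                "feature_id": self.lexa.feature_id,
                "start_1based": self.lexa.start + 1,
                "end_1based": self.lexa.end,
                "strand": self.lexa.strand,
                "detection_score": round(self.lexa.detection_score, 3),
                "detection_method": self.lexa.detection_method,
            },
            "csb": None
            if self.csb is None
            else {
                "start_1based": self.csb.hit.start + 1,
                "end_1based": self.csb.hit.end,
                "strand": self.csb.hit.strand,
                "sequence": self.csb.hit.sequence,
                "hi": round(self.csb.hit.hi, 2),
                "distance_to_lexa_start": self.csb.distance_to_lexa_start,
            },
            "n_psbs": len(self.psb_his),
            "hi_c1": None if self.hi_c1 is None else round(self.hi_c1, 2),
            "hi_c2": None if self.hi_c2 is None else round(self.hi_c2, 2),
        }
        return json.dumps(doc, indent=2, **kwargs)


def load_lexa_references() -> dict[str, str]:
    """Packaged reference LexA protein sequences, keyed by identifier."""
    from Bio import SeqIO

    ref = resources.files("sosdep.data").joinpath("lexa_references.faa")
    with resources.as_file(ref) as path:
        return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def _make_aligner():
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def find_lexa(
    genome: GenomeRecord,
    references: dict[str, str] | None = None,
    min_score_per_len: float = DEFAULT_LEXA_SCORE_PER_LEN,
) -> LexaLocus | None:
    """Best LexA candidate CDS by local protein alignment, or None.

    Every CDS translation within a loose length band of a reference is aligned
    against it; the score is normalized by reference length.  The best CDS
    above ``min_score_per_len`` wins; ties break toward the lowest start.
    """
    if references is None:
        references = load_lexa_references()
    if not genome.cds_list or not references:
        return None
    aligner = _make_aligner()
    best: tuple[float, int, LexaLocus] | None = None
    for cds in genome.cds_list:
        try:
            prot = genome.cds_translation(cds).rstrip("*")
        except Exception:
            continue
        if not prot or "*" in prot:
            continue
        for ref_seq in references.values():
            if not 0.5 <= len(prot) / len(ref_seq) <= 2.0:
                continue
            try:
                score = aligner.score(ref_seq, prot)
            except ValueError:  # non-standard residues
                continue
            norm = score / len(ref_seq)
            if norm < min_score_per_len:
                continue
            locus = LexaLocus(
                cds.feature_id, cds.start, cds.end, cds.strand, norm
            )
            key = (-norm, cds.start)
            if best is None or key < (-best[0], best[1]):
                best = (norm, cds.start, locus)
    return best[2] if best else None


def find_csb(
    genome: GenomeRecord,
    lexa: LexaLocus,
    matrix: SosBoxMatrix | None = None,
    upstream_len: int = 300,
    into_gene_len: int = 50,
    csb_cutoff: float = DEFAULT_CSB_CUTOFF,
    mismatch_allowance: int = 0,
) -> CsbEvidence | None:
    """Lowest-HI operator in the lexA promoter window, if it clears the cutoff."""
    matrix = matrix or default_matrix()
    lexa_cds = next(
        (c for c in genome.cds_list if c.feature_id == lexa.feature_id), None
    )
    if lexa_cds is None:
        return None
    single = GenomeRecord(genome.replicon_id, genome.sequence, [lexa_cds])
    promoters = extract_promoters(single, None, upstream_len, into_gene_len)
    best: PsbHit | None = None
    for prom in promoters:
        for hit in scan_region(
            matrix, genome, (prom.start, prom.end), mismatch_allowance
        ):
            if best is None or (hit.hi, hit.start) < (best.hi, best.start):
                best = hit
    if best is None or best.hi > csb_cutoff:
        return None
    if lexa.strand == "+":
        dist = lexa.start - best.end
    else:
        dist = best.start - lexa.end
    return CsbEvidence(best, dist)


def survey_psbs(
    genome: GenomeRecord,
    matrix: SosBoxMatrix | None = None,
    scope: str = "whole_genome",
    mismatch_allowance: int = 0,
    upstream_len: int = 300,
    into_gene_len: int = 50,
) -> list[PsbHit]:
    """All deduplicated PSB hits in scope, sorted by coordinate.

    ``scope="whole_genome"`` scans the full replicon (the host-side default);
    ``scope="promoters"`` restricts to CDS promoter windows, deduplicating
    hits shared by overlapping windows.
    """
    matrix = matrix or default_matrix()
    if scope == "whole_genome":
        return scan_region(matrix, genome, None, mismatch_allowance)
    if scope != "promoters":
        raise ValueError(f"unknown scope {scope!r}")
    seen: dict[tuple[int, int], PsbHit] = {}
    for prom in extract_promoters(genome, None, upstream_len, into_gene_len):
        for hit in scan_region(
            matrix, genome, (prom.start, prom.end), mismatch_allowance
        ):
            seen.setdefault((hit.start, hit.end), hit)
    return [seen[k] for k in sorted(seen)]


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb KDE bandwidth for 1-D data."""
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 0.0
    return 0.9 * spread * n ** (-0.2)


def _cluster_labels(
    values: np.ndarray, method: str, bandwidth: float | None
) -> np.ndarray | None:
    """1-D cluster labels for sorted values, or None when degenerate."""
    x = values.reshape(-1, 1)
    if method == "meanshift":
        from sklearn.cluster import MeanShift

        bw = bandwidth if bandwidth is not None else silverman_bandwidth(values)
        if bw <= 0:
            return None
        return MeanShift(bandwidth=bw).fit_predict(x)
    if method == "kmeans2":
        from sklearn.cluster import KMeans

        if np.ptp(values) == 0:
            return None
        init = np.percentile(values, [25, 75]).reshape(-1, 1)
        return KMeans(n_clusters=2, init=init, n_init=1).fit_predict(x)
    if method == "otsu":
        from skimage.filters import threshold_otsu

        if np.ptp(values) == 0:
            return None
        thr = threshold_otsu(values, nbins=256)
        return (values > thr).astype(int)
    raise ValueError(f"unknown clustering method {method!r}")


def derive_thresholds(
    his: Sequence[float],
    method: str = "meanshift",
    bandwidth: float | None = None,
    min_psb_count: int = DEFAULT_MIN_PSB_COUNT,
) -> ThresholdResult:
    """Split 1-D HI values into low/high clusters and take HI_C1/HI_C2.

    The low and high clusters are anchored at the two most populous clusters
    (ordered by mean).  Mean Shift on small samples can split off tiny
    satellite clusters at the extremes — e.g. the genome's own near-consensus
    operators sitting below the bulk of the low component; a value below
    every member of the low cluster is unambiguously on the binding side, so
    minor clusters outside the dominant pair are merged into the nearest
    extreme.  Clusters strictly between the dominant pair belong to neither
    and their members land in the SuP gap between the thresholds.
    HI_C1 = max(low cluster), HI_C2 = min(high cluster); HI_C1 < HI_C2 is
    required, otherwise the genome is reported AMBIGUOUS_CLUSTERING.
    Input order never affects the result (values are sorted first).
    """
    values = np.sort(np.asarray(list(his), dtype=float))
    if len(values) < min_psb_count:
        return ThresholdResult(
            ok=False, reason=f"only {len(values)} PSBs (< {min_psb_count})"
        )
    labels = _cluster_labels(values, method, bandwidth)
    if labels is None:
        return ThresholdResult(ok=False, reason="degenerate HI distribution")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        return ThresholdResult(ok=False, reason="single cluster")
    means = {lab: float(values[labels == lab].mean()) for lab in uniq}
    sizes = {lab: int((labels == lab).sum()) for lab in uniq}
    dominant = sorted(uniq, key=lambda lab: (-sizes[lab], means[lab]))[:2]
    low_anchor, high_anchor = sorted(means[lab] for lab in dominant)
    low_mask = np.isin(labels, [lab for lab in uniq if means[lab] <= low_anchor])
    high_mask = np.isin(labels, [lab for lab in uniq if means[lab] >= high_anchor])
    low = values[low_mask]
    high = values[high_mask]
    hi_c1, hi_c2 = float(low.max()), float(high.min())
    if not hi_c1 < hi_c2:
        return ThresholdResult(ok=False, reason="cluster extrema overlap")
    return ThresholdResult(
        ok=True,
        hi_c1=hi_c1,
        hi_c2=hi_c2,
        low_cluster=[float(v) for v in low],
        high_cluster=[float(v) for v in high],
    )


def build_host_profile(
    genome: GenomeRecord,
    matrix: SosBoxMatrix | None = None,
    references: dict[str, str] | None = None,
    scope: str = "whole_genome",
    method: str = "meanshift",
    bandwidth: float | None = None,
    csb_cutoff: float = DEFAULT_CSB_CUTOFF,
    min_psb_count: int = DEFAULT_MIN_PSB_COUNT,
    mismatch_allowance: int = 0,
    upstream_len: int = 300,
    into_gene_len: int = 50,
    lexa_score_per_len: float = DEFAULT_LEXA_SCORE_PER_LEN,
) -> HostProfile:
    """Chain LexA detection -> CSB confirmation -> PSB survey -> thresholds.

    The profile's status records the first failing step (NO_LEXA, NO_CSB,
    AMBIGUOUS_CLUSTERING) or OK.  The PSB survey is reported even when
    clustering fails, for diagnostics.
    """
    matrix = matrix or default_matrix()
    profile = HostProfile(genome_id=genome.replicon_id, status=STATUS_OK)
    lexa = find_lexa(genome, references, lexa_score_per_len)
    if lexa is None:
        profile.status = STATUS_NO_LEXA
        return profile
    profile.lexa = lexa
    csb = find_csb(
        genome, lexa, matrix, upstream_len, into_gene_len, csb_cutoff,
        mismatch_allowance,
    )
    if csb is None:
        profile.status = STATUS_NO_CSB
        return profile
    profile.csb = csb
    hits = survey_psbs(
        genome, matrix, scope, mismatch_allowance, upstream_len, into_gene_len
    )
    profile.psb_hits = hits
    profile.psb_his = [h.hi for h in hits]
    result = derive_thresholds(profile.psb_his, method, bandwidth, min_psb_count)
    if not result.ok:
        profile.status = STATUS_AMBIGUOUS
        return profile
    profile.hi_c1 = result.hi_c1
    profile.hi_c2 = result.hi_c2
    profile.low_cluster = result.low_cluster
    profile.high_cluster = result.high_cluster
    return profile
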
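"""Per-sequence genomic statistics and phage-vs-host compositional distances.

SOS-independent and SOS-dependent prophages differ systematically in coding
architecture (coding density, CDS overlap, intergenic GC, protein sizes) and
in how far their nucleotide/codon composition sits from their host's.  This
module computes those statistics for any annotated sequence:

* PCD (protein-coding density): fraction of bases covered by >= 1 CDS.
* PCO (proportion of CDS overlap): base-wise pairwise overlap between CDSs,
  sum_b C(cov_b, 2), divided by total CDS bases sum_b cov_b.  For two CDSs
  [0,100) and [50,150) this gives 50/200.
* IR GC: GC content of the intergenic complement of the CDS union.
* Dc(phage, host): cosine distance between 64-dim codon frequency vectors.
* k-mer divergence: cosine distance between k-mer frequency vectors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cosine as _cosine_distance

from .genome_io import CdsFeature, GenomeRecord, ProphageRegion
from .sosbox_scoring import BASES, reverse_complement

CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


@dataclass(frozen=True)
class FeatureVector:
    genome_size: int
    gc: float
    pcd: float | None = None
    pco: float | None = None
    ir_gc: float | None = None
    mean_protein_size: float | None = None
    codon_freq: np.ndarray | None = None


@dataclass(frozen=True)
class PhageHostDistance:
    codon_distance: float
    nt_divergence: dict[int, float]


def gc_content(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def _coverage(length: int, cds_list: Sequence[CdsFeature]) -> np.ndarray:
    cov = np.zeros(length, dtype=np.int32)
    for cds in cds_list:
        cov[cds.start : cds.end] += 1
    return cov


def slice_record(genome: GenomeRecord, region: ProphageRegion) -> GenomeRecord:
    """Sub-record for a prophage region, CDSs clipped and shifted to it."""
    cds = []
    for c in genome.cds_list:
        if c.start < region.end and c.end > region.start:
            cds.append(
                CdsFeature(
                    feature_id=c.feature_id,
                    start=max(c.start, region.start) - region.start,
                    end=min(c.end, region.end) - region.start,
                    strand=c.strand,
                    product=c.product,
                    translation=c.translation,
                )
            )
    return GenomeRecord(
        replicon_id=region.prophage_id,
        sequence=genome.sequence[region.start : region.end],
        cds_list=cds,
    )


def codon_frequencies(record: GenomeRecord) -> np.ndarray | None:
    """64-vector of codon proportions over all annotated, in-frame CDSs.

    Codons are read on the CDS strand from the annotated start; the trailing
    partial codon (if any) is dropped and codons containing N are skipped.
    Returns None when no codon could be counted.
    """
    counts = np.zeros(64, dtype=np.int64)
    for cds in record.cds_list:
        seq = record.sequence[cds.start : cds.end]
        if cds.strand == "-":
            seq = reverse_complement(seq)
        for i in range(0, len(seq) - len(seq) % 3, 3):
            idx = _CODON_INDEX.get(seq[i : i + 3])
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def kmer_frequencies(seq: str, k: int) -> np.ndarray:
    """Normalized k-mer frequency vector (strand-naive); N-containing k-mers skipped."""
    if not 1 <= k <= 4:
        raise ValueError(f"k must be in 1..4, got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    seq = seq.upper()
    counts = np.zeros(4**k, dtype=np.int64)
    index = {"".join(p): i for i, p in enumerate(itertools.product(BASES, repeat=k))}
    for i in range(len(seq) - k + 1):
        idx = index.get(seq[i : i + k])
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def feature_vector(record: GenomeRecord) -> FeatureVector:
    """All per-sequence statistics; annotation-dependent fields are None
    when the record carries no CDS features."""
    n = len(record)
    gc = gc_content(record.sequence)
    if not record.cds_list:
        return FeatureVector(genome_size=n, gc=gc)
    cov = _coverage(n, record.cds_list)
    covered = int((cov > 0).sum())
    total_cds_bases = int(cov.sum())
    overlap_pairs = int((cov.astype(np.int64) * (cov - 1) // 2).sum())
    intergenic = "".join(
        ch for ch, c in zip(record.sequence, cov) if c == 0
    )
    sizes = [max((c.end - c.start) // 3 - 1, 0) for c in record.cds_list]
    return FeatureVector(
        genome_size=n,
        gc=gc,
        pcd=covered / n,
        pco=overlap_pairs / total_cds_bases if total_cds_bases else 0.0,
        ir_gc=gc_content(intergenic) if intergenic else None,
        mean_protein_size=float(np.mean(sizes)) if sizes else None,
        codon_freq=codon_frequencies(record),
    )


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    if not u.any() or not v.any():
        raise ValueError("cosine distance undefined for a zero vector")
    return float(_cosine_distance(u, v))


def codon_cosine_distance(phage: GenomeRecord, host: GenomeRecord) -> float:
    """Dc(phage, host): 1 - cosine similarity of codon frequency vectors."""
    fp = codon_frequencies(phage)
    fh = codon_frequencies(host)
    if fp is None or fh is None:
        raise ValueError("codon distance requires CDS annotations on both records")
    return _cosine(fp, fh)


def nt_divergence(phage_seq: str, host_seq: str, k: int = 1) -> float:
    """Cosine distance between normalized k-mer frequency vectors."""
    return _cosine(kmer_frequencies(phage_seq, k), kmer_frequencies(host_seq, k))


def phage_host_distance(
    phage: GenomeRecord, host: GenomeRecord, ks: Sequence[int] = (1, 2)
) -> PhageHostDistance:
    return PhageHostDistance(
        codon_distance=codon_cosine_distance(phage, host),
        nt_divergence={
            k: nt_divergence(phage.sequence, host.sequence, k) for k in ks
        },
    )
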
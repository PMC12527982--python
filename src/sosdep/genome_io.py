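"""Genome, annotation and prophage-region I/O with a single coordinate convention.

All internal coordinates are 0-based half-open intervals on the forward strand.
GenBank and GFF3 inputs (1-based inclusive) are shifted on read; BED is already
half-open.  Reports emitted elsewhere convert back to 1-based inclusive.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord


class GenomeIOError(ValueError):
    """Unreadable input, mismatched replicon IDs, or out-of-bounds features."""


@dataclass(frozen=True)
class CdsFeature:
    feature_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    translation: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GenomeIOError(f"bad strand {self.strand!r} for {self.feature_id}")
        if not 0 <= self.start < self.end:
            raise GenomeIOError(
                f"bad CDS interval [{self.start}, {self.end}) for {self.feature_id}"
            )


@dataclass(frozen=True)
class PromoterRegion:
    parent_feature_id: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class ProphageRegion:
    prophage_id: str
    replicon_id: str
    start: int
    end: int
    completeness_label: str | None = None


@dataclass
class GenomeRecord:
    replicon_id: str
    sequence: str
    cds_list: list[CdsFeature] = field(default_factory=list)
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeIOError(f"empty sequence for replicon {self.replicon_id}")
        self.sequence = self.sequence.upper()
        for cds in self.cds_list:
            if cds.end > len(self.sequence):
                raise GenomeIOError(
                    f"CDS {cds.feature_id} [{cds.start}, {cds.end}) outside "
                    f"replicon {self.replicon_id} (length {len(self.sequence)})"
                )
        self.cds_list = sorted(self.cds_list, key=lambda c: (c.start, c.end))

    def __len__(self) -> int:
        return len(self.sequence)

    def cds_translation(self, cds: CdsFeature) -> str:
        """Annotated translation if present, else a direct frame-0 translation."""
        if cds.translation:
            return cds.translation
        frag = self.sequence[cds.start : cds.end]
        if cds.strand == "-":
            frag = str(Seq(frag).reverse_complement())
        frag = frag[: len(frag) - len(frag) % 3]
        return str(Seq(frag).translate()).rstrip("*")


def _cds_from_seqfeature(feature, index: int) -> CdsFeature:
    quals = feature.qualifiers
    fid = (
        quals.get("locus_tag", quals.get("gene", quals.get("protein_id", [None])))[0]
        or f"cds_{index:05d}"
    )
    translation = quals.get("translation", [None])[0]
    return CdsFeature(
        feature_id=fid,
        start=int(feature.location.start),
        end=int(feature.location.end),
        strand="+" if feature.location.strand != -1 else "-",
        product=quals.get("product", [""])[0],
        translation=translation,
    )


def _read_gff_cds(annotation_path: str | Path) -> dict[str, list[CdsFeature]]:
    import gffutils

    db = gffutils.create_db(
        str(annotation_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    per_replicon: dict[str, list[CdsFeature]] = {}
    for i, feat in enumerate(db.features_of_type("CDS", order_by=("seqid", "start"))):
        fid = (
            feat.attributes.get("locus_tag", feat.attributes.get("ID", [None]))[0]
            or f"cds_{i:05d}"
        )
        cds = CdsFeature(
            feature_id=fid,
            start=feat.start - 1,  # GFF3 is 1-based inclusive
            end=feat.end,
            strand="-" if feat.strand == "-" else "+",
            product=feat.attributes.get("product", [""])[0],
        )
        per_replicon.setdefault(feat.seqid, []).append(cds)
    return per_replicon


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.startswith(">") else "genbank"
    raise GenomeIOError(f"{path} is empty")


def read_genome(
    path: str | Path, annotation_path: str | Path | None = None
) -> list[GenomeRecord]:
    """Read a GenBank file, or a FASTA plus a GFF3 with CDS features.

    Returns one :class:`GenomeRecord` per replicon, CDSs in 0-based half-open
    coordinates sorted by start.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"no such file: {path}")
    fmt = _sniff_format(path)
    records: list[GenomeRecord] = []
    if fmt == "genbank":
        for rec in SeqIO.parse(str(path), "genbank"):
            cds = [
                _cds_from_seqfeature(f, i)
                for i, f in enumerate(rec.features)
                if f.type == "CDS"
            ]
            records.append(
                GenomeRecord(rec.id, str(rec.seq), cds, source_path=str(path))
            )
    else:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise GenomeIOError(f"no FASTA records in {path}")
        ann = _read_gff_cds(annotation_path) if annotation_path else {}
        unknown = set(ann) - set(seqs)
        if unknown:
            raise GenomeIOError(
                f"annotation replicon IDs not in FASTA: {sorted(unknown)}"
            )
        for rid, seq in seqs.items():
            records.append(
                GenomeRecord(rid, seq, ann.get(rid, []), source_path=str(path))
            )
    if not records:
        raise GenomeIOError(f"no sequence records in {path}")
    return records


def write_genome(genome: GenomeRecord, path: str | Path) -> None:
    """Write a GenomeRecord as a GenBank flat file (byte-stable: fixed date)."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.replicon_id,
        name=genome.replicon_id[:16],
        description="synthetic replicon",
        annotations={"molecule_type": "DNA", "date": "01-JAN-1980"},
    )
    for cds in genome.cds_list:
        quals = {"locus_tag": [cds.feature_id]}
        if cds.product:
            quals["product"] = [cds.product]
        if cds.translation:
            quals["translation"] = [cds.translation]
        rec.features.append(
            SeqFeature(
                FeatureLocation(cds.start, cds.end, strand=1 if cds.strand == "+" else -1),
                type="CDS",
                qualifiers=quals,
            )
        )
    SeqIO.write([rec], str(path), "genbank")


def read_prophage_regions(
    path: str | Path, genomes: Sequence[GenomeRecord]
) -> list[ProphageRegion]:
    """Read prophage intervals from BED (0-based half-open) or GFF3 (1-based).

    Regions are validated against the replicon set: unknown replicon IDs and
    out-of-bounds intervals raise :class:`GenomeIOError`.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"no such file: {path}")
    lengths = {g.replicon_id: len(g) for g in genomes}
    text = path.read_text().splitlines()
    is_gff = path.suffix.lower() in {".gff", ".gff3"} or any(
        line.startswith("##gff-version") for line in text[:5]
    )
    regions: list[ProphageRegion] = []
    n = 0
    for line in text:
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if is_gff:
            if len(fields) < 9:
                raise GenomeIOError(f"malformed GFF3 line in {path}: {line!r}")
            rid, start, end = fields[0], int(fields[3]) - 1, int(fields[4])
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            pid = attrs.get("ID", f"prophage_{n:03d}")
        else:
            if len(fields) < 3:
                raise GenomeIOError(f"malformed BED line in {path}: {line!r}")
            rid, start, end = fields[0], int(fields[1]), int(fields[2])
            pid = fields[3] if len(fields) > 3 else f"prophage_{n:03d}"
        if rid not in lengths:
            raise GenomeIOError(f"unknown replicon ID {rid!r} in {path}")
        if not 0 <= start < end <= lengths[rid]:
            raise GenomeIOError(
                f"region {pid} [{start}, {end}) outside replicon {rid} "
                f"(length {lengths[rid]})"
            )
        regions.append(ProphageRegion(pid, rid, start, end))
        n += 1
    return regions


def write_prophage_bed(regions: Sequence[ProphageRegion], path: str | Path) -> None:
    lines = [
        f"{r.replicon_id}\t{r.start}\t{r.end}\t{r.prophage_id}" for r in regions
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def extract_promoters(
    genome: GenomeRecord,
    region: ProphageRegion | None = None,
    upstream_len: int = 300,
    into_gene_len: int = 50,
    circular: bool = False,
) -> list[PromoterRegion]:
    """Promoter window for each CDS: ``upstream_len`` bases upstream of the
    translation start plus ``into_gene_len`` bases into the CDS, on the CDS
    strand.

    With ``region`` given, only CDSs overlapping the region contribute.
    Windows are truncated at replicon ends unless ``circular``, in which case
    the wrapped part is emitted as a second interval.  Overlapping windows from
    different CDSs are not merged.
    """
    n = len(genome)
    out: list[PromoterRegion] = []
    for cds in genome.cds_list:
        if region is not None and not (cds.start < region.end and cds.end > region.start):
            continue
        if cds.strand == "+":
            lo, hi = cds.start - upstream_len, min(cds.start + into_gene_len, cds.end)
        else:
            lo, hi = max(cds.end - into_gene_len, cds.start), cds.end + upstream_len
        if circular:
            if lo < 0:
                out.append(PromoterRegion(cds.feature_id, (lo + n) % n, n, cds.strand))
            if hi > n:
                out.append(PromoterRegion(cds.feature_id, 0, hi - n, cds.strand))
        lo, hi = max(lo, 0), min(hi, n)
        if hi > lo:
            out.append(PromoterRegion(cds.feature_id, lo, hi, cds.strand))
    return out


def roundtrip_genome(genome: GenomeRecord) -> GenomeRecord:
    """Write to a temporary GenBank file and read back (testing helper)."""
    with tempfile.NamedTemporaryFile(suffix=".gbk", delete=False) as fh:
        tmp = fh.name
    try:
        write_genome(genome, tmp)
        return read_genome(tmp)[0]
    finally:
        Path(tmp).unlink(missing_ok=True)
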
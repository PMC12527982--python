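"""SOS-box count matrix, Heterology Index scoring, and both-strand operator scanning.

The LexA repressor of the bacterial SOS response binds a conserved, palindromic
operator (the "SOS box"; canonical *E. coli* form 5'-TACTG(TA)5CAGTA-3', 20 bp).
How well an arbitrary 20-mer is predicted to bind LexA is quantified here by the
Heterology Index (HI): the summed log-ratio of consensus-base counts to
observed-base counts across the motif, under a position count matrix built from
an alignment of experimentally characterized operators.  HI = 0 at the
consensus; larger HI means weaker predicted binding.

Candidate operators ("potential SOS boxes", PSBs) are defined by an exact (or
near-exact) match to the invariant palindromic core CTG...CAG — positions 3-5
and 16-18 of the 20-mer in 1-based coordinates — scanned on both strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Canonical E. coli SOS box, 5'-TACTG(TA)5CAGTA-3'.  It is its own reverse
#: complement, which is why a single-strand consensus describes a
#: double-stranded binding site.
CANONICAL_BOX = "TACTGTATATATATACAGTA"

#: Invariant core of the canonical box: CTG at motif offsets 2-4 and CAG at
#: 15-17 (0-based).  These six positions are fully conserved in the packaged
#: operator alignment.
DEFAULT_CORE = ((2, "C"), (3, "T"), (4, "G"), (15, "C"), (16, "A"), (17, "G"))

DEFAULT_PSEUDOCOUNT = 0.5


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MatrixFormatError(ValueError):
    """Raised for malformed matrix files or inconsistent site alignments."""


@dataclass(frozen=True)
class SosBoxMatrix:
    """Position count matrix over a fixed-length operator motif.

    Attributes
    ----------
    motif_length:
        Motif length L (20 for the canonical box).
    counts:
        L x 4 integer array of base counts per position, columns ordered
        A, C, G, T.  Every row sums to ``n_sites``.
    pseudocount:
        Additive smoothing constant used in the HI log-ratio.
    consensus:
        Per-position argmax base string; ties are broken toward the canonical
        E. coli box, then alphabetically.  Always recomputed from counts.
    core_positions:
        ``(offset, base)`` pairs a window must match (up to the scanner's
        mismatch allowance) to count as a PSB candidate.
    n_sites:
        Number of aligned sites behind ``counts``.
    """

    motif_length: int
    counts: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    consensus: str = field(default="", compare=False)
    core_positions: tuple[tuple[int, str], ...] = DEFAULT_CORE
    n_sites: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (self.motif_length, 4):
            raise MatrixFormatError(
                f"counts shape {counts.shape} != ({self.motif_length}, 4)"
            )
        if (counts < 0).any():
            raise MatrixFormatError("negative counts")
        if self.pseudocount <= 0:
            raise MatrixFormatError("pseudocount must be positive")
        row_sums = counts.sum(axis=1)
        n_sites = self.n_sites or int(row_sums[0])
        if not (row_sums == n_sites).all():
            raise MatrixFormatError("column counts do not all sum to n_sites")
        for pos, base in self.core_positions:
            if not 0 <= pos < self.motif_length or base not in BASES:
                raise MatrixFormatError(f"invalid core position {(pos, base)}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "n_sites", n_sites)
        object.__setattr__(self, "consensus", self._compute_consensus())

    def _compute_consensus(self) -> str:
        out = []
        for i in range(self.motif_length):
            row = self.counts[i]
            top = row.max()
            winners = [BASES[j] for j in range(4) if row[j] == top]
            canon = CANONICAL_BOX[i] if i < len(CANONICAL_BOX) else None
            out.append(canon if canon in winners else winners[0])
        return "".join(out)

    @property
    def penalties(self) -> np.ndarray:
        """L x 4 array of per-position HI contributions ln((n_max+p)/(n_b+p))."""
        p = self.pseudocount
        n_cons = np.array(
            [self.counts[i, _BASE_INDEX[self.consensus[i]]] for i in range(self.motif_length)],
            dtype=float,
        )
        return np.log((n_cons[:, None] + p) / (self.counts + p))

    # -- construction ------------------------------------------------------

    @classmethod
    def from_sites(
        cls,
        aligned_sites: Sequence[str],
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        core_positions: tuple[tuple[int, str], ...] = DEFAULT_CORE,
        symmetrize: bool = False,
    ) -> "SosBoxMatrix":
        """Build a count matrix from aligned operator sequences.

        With ``symmetrize=True`` the counts are made palindromic by adding, at
        every position i, the complement-base counts of the mirror position
        L-1-i.  For a palindromic operator this pools the two strands of each
        site, makes HI strictly strand-symmetric, and doubles ``n_sites``.
        """
        sites = [s.upper() for s in aligned_sites]
        if len(sites) < 2:
            raise MatrixFormatError("need at least two aligned sites")
        length = len(sites[0])
        if any(len(s) != length for s in sites):
            raise MatrixFormatError("ragged site lengths")
        counts = np.zeros((length, 4), dtype=np.int64)
        for s in sites:
            for i, b in enumerate(s):
                if b not in _BASE_INDEX:
                    raise MatrixFormatError(f"invalid base {b!r} in site {s}")
                counts[i, _BASE_INDEX[b]] += 1
        if symmetrize:
            flipped = counts[::-1, ::-1]  # complement order under ACGT is TGCA
            counts = counts + flipped
        return cls(
            motif_length=length,
            counts=counts,
            pseudocount=pseudocount,
            core_positions=core_positions,
        )

    # -- serialization -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        core = ",".join(
            f"{pos + 1}:{base}" for pos, base in self.core_positions
        )
        lines = [
            f"#length={self.motif_length}",
            f"#pseudocount={self.pseudocount}",
            f"#n_sites={self.n_sites}",
            f"#core={core}",
            "pos\tA\tC\tG\tT",
        ]
        for i in range(self.motif_length):
            lines.append(
                "\t".join([str(i + 1)] + [str(int(c)) for c in self.counts[i]])
            )
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SosBoxMatrix":
        meta: dict[str, str] = {}
        rows: list[list[int]] = []
        header_seen = False
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line.split("\t") != ["pos", "A", "C", "G", "T"]:
                    raise MatrixFormatError(f"bad header line: {line!r}")
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise MatrixFormatError(f"bad matrix row: {line!r}")
            rows.append([int(x) for x in fields[1:]])
        if not rows:
            raise MatrixFormatError("matrix file contains no count rows")
        length = int(meta.get("length", len(rows)))
        if length != len(rows):
            raise MatrixFormatError("row count disagrees with #length")
        core = DEFAULT_CORE
        if "core" in meta:
            parsed = []
            for item in meta["core"].split(","):
                pos_s, _, base = item.partition(":")
                parsed.append((int(pos_s) - 1, base))
            core = tuple(parsed)
        return cls(
            motif_length=length,
            counts=np.array(rows, dtype=np.int64),
            pseudocount=float(meta.get("pseudocount", DEFAULT_PSEUDOCOUNT)),
            core_positions=core,
            n_sites=int(meta.get("n_sites", 0)),
        )


_DEFAULT_MATRIX: SosBoxMatrix | None = None


def default_matrix() -> SosBoxMatrix:
    """The packaged E. coli-derived SOS-box matrix (cached)."""
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        ref = resources.files("sosdep.data").joinpath("sosbox_matrix_ecoli.tsv")
        with resources.as_file(ref) as path:
            _DEFAULT_MATRIX = SosBoxMatrix.load(path)
    return _DEFAULT_MATRIX


def build_matrix(
    aligned_sites: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    **kwargs,
) -> SosBoxMatrix:
    """Functional alias for :meth:`SosBoxMatrix.from_sites`."""
    return SosBoxMatrix.from_sites(aligned_sites, pseudocount, **kwargs)


def hi_score(matrix: SosBoxMatrix, window: str) -> float:
    """Heterology Index of a motif-length window.

    HI = sum_i ln[(counts[i][consensus[i]] + p) / (counts[i][window[i]] + p)].
    Zero at the consensus, non-negative everywhere, additive over positions.
    """
    window = window.upper()
    if len(window) != matrix.motif_length:
        raise ValueError(
            f"window length {len(window)} != motif length {matrix.motif_length}"
        )
    pen = matrix.penalties
    total = 0.0
    for i, b in enumerate(window):
        j = _BASE_INDEX.get(b)
        if j is None:
            raise ValueError(f"invalid base {b!r} at window position {i}")
        total += pen[i, j]
    return float(total)


@dataclass(frozen=True)
class PsbHit:
    """A located potential SOS box (PSB).

    ``sequence`` is strand-oriented: for a minus-strand hit it is the reverse
    complement of the genome slice ``[start, end)``.
    """

    replicon_id: str
    start: int
    end: int
    strand: str
    sequence: str
    hi: float
    context_feature_id: str | None = None


def _core_mismatch_counts(
    codes: np.ndarray, matrix: SosBoxMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window-start mismatch counts to the core, forward and reverse.

    ``codes`` encodes the sequence as ints (A0 C1 G2 T3, other 4).  A window
    [s, s+L) matches the core in reverse orientation when its reverse
    complement matches in forward orientation, i.e. when position L-1-o holds
    the complement of the required base for each core pair (o, b).
    """
    L = matrix.motif_length
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int32), np.zeros(0, dtype=np.int32)
    fwd = np.zeros(n_win, dtype=np.int32)
    rev = np.zeros(n_win, dtype=np.int32)
    for off, base in matrix.core_positions:
        want = _BASE_INDEX[base]
        fwd += codes[off : off + n_win] != want
        mirror = L - 1 - off
        want_rc = 3 - want  # complement under ACGT coding
        rev += codes[mirror : mirror + n_win] != want_rc
    return fwd, rev


def scan_region(
    matrix: SosBoxMatrix,
    genome,
    interval: tuple[int, int] | None = None,
    mismatch_allowance: int = 0,
    hi_cap: float | None = None,
) -> list[PsbHit]:
    """Slide the motif over both strands of ``interval`` and return PSB hits.

    A window qualifies when it matches ``matrix.core_positions`` with at most
    ``mismatch_allowance`` mismatches (in either orientation) and, when
    ``hi_cap`` is set, scores ``hi <= hi_cap``.  Windows containing N are
    skipped.  When both orientations of one interval qualify, the lower-HI
    orientation is kept (tie: plus strand), so each genomic interval yields at
    most one hit.  Output is sorted by start coordinate.
    """
    seq = genome.sequence
    L = matrix.motif_length
    lo, hi_bound = (0, len(seq)) if interval is None else interval
    lo = max(lo, 0)
    hi_bound = min(hi_bound, len(seq))
    if hi_bound - lo < L:
        return []
    sub = seq[lo:hi_bound].upper()
    codes = np.frombuffer(sub.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    codes = lut[codes]
    fwd_mm, rev_mm = _core_mismatch_counts(codes, matrix)
    candidates = np.nonzero(
        (fwd_mm <= mismatch_allowance) | (rev_mm <= mismatch_allowance)
    )[0]
    pen = matrix.penalties
    hits: list[PsbHit] = []
    for s in candidates:
        win_codes = codes[s : s + L]
        if (win_codes == 4).any():  # N or other ambiguity code
            continue
        window = sub[s : s + L]
        options: list[tuple[float, int, str, str]] = []
        if fwd_mm[s] <= mismatch_allowance:
            hi_f = float(pen[np.arange(L), win_codes].sum())
            options.append((hi_f, 0, "+", window))
        if rev_mm[s] <= mismatch_allowance:
            rc = reverse_complement(window)
            rc_codes = 3 - win_codes[::-1]
            hi_r = float(pen[np.arange(L), rc_codes].sum())
            options.append((hi_r, 1, "-", rc))
        if len(options) == 2 and abs(options[0][0] - options[1][0]) <= 1e-9:
            options = options[:1]  # tie between strands keeps plus
        hi_val, _, strand, oriented = min(options)
        if hi_cap is not None and hi_val > hi_cap:
            continue
        hits.append(
            PsbHit(
                replicon_id=genome.replicon_id,
                start=lo + int(s),
                end=lo + int(s) + L,
                strand=strand,
                sequence=oriented,
                hi=hi_val,
            )
        )
    return hits


def assign_context(hits: Iterable[PsbHit], genome) -> list[PsbHit]:
    """Annotate each hit with the nearest downstream CDS on the hit's strand."""
    from dataclasses import replace

    plus_starts = sorted(
        (c.start, c.feature_id) for c in genome.cds_list if c.strand == "+"
    )
    minus_ends = sorted(
        (c.end, c.feature_id) for c in genome.cds_list if c.strand == "-"
    )
    import bisect

    out = []
    for h in hits:
        ctx = None
        if h.strand == "+" and plus_starts:
            i = bisect.bisect_left(plus_starts, (h.start, ""))
            if i < len(plus_starts):
                ctx = plus_starts[i][1]
        elif h.strand == "-" and minus_ends:
            i = bisect.bisect_right(minus_ends, (h.end, "￿"))
            if i > 0:
                ctx = minus_ends[i - 1][1]
        out.append(replace(h, context_feature_id=ctx))
    return out
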
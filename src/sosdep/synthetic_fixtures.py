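"""Synthetic annotated genomes with planted operators and known truth labels.

The generator emulates the statistical structure the classifier relies on: a
host replicon carrying a *lexA* gene with a consensus operator 80 bp upstream,
a genome-wide population of planted operator candidates whose HI values follow
a two-component (low ~ N(7,1) / high ~ N(22,2)) mixture matching the bimodal
*E. coli* distribution, and prophage regions whose promoter operators are
designed to a chosen HI_min.  Because the background is scrubbed of the
CTG-N10-CAG core pattern, the planted candidates are the *only* PSBs, giving
exact truth tables for end-to-end tests.

Everything is deterministic in the seed, byte-stable on disk.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import (
    CdsFeature,
    GenomeRecord,
    ProphageRegion,
    write_genome,
    write_prophage_bed,
)
from .host_profiling import load_lexa_references
from .sosbox_scoring import (
    BASES,
    SosBoxMatrix,
    default_matrix,
    hi_score,
)

CORE_PATTERN = re.compile(r"(?=(CTG.{10}CAG))", flags=re.DOTALL)

#: One codon per amino acid for deterministic back-translation.
_CODON_FOR_AA = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


class FixtureError(ValueError):
    """Infeasible fixture spec (packing or unreachable HI target)."""


@dataclass
class FixtureSpec:
    seed: int = 0
    replicon_length: int | None = None  # None: computed from content
    n_background_cds: int = 30
    low_hi_targets: tuple[float, ...] = ()
    high_hi_targets: tuple[float, ...] = ()
    #: (length_bp, designed_hi_min or None, truth_label)
    prophages: tuple[tuple[int, float | None, str], ...] = ()
    gc_background: float = 0.5
    plant_lexa: bool = True
    plant_csb: bool = True
    design_tolerance: float = 0.25


def default_spec(seed: int) -> FixtureSpec:
    """Study-condition defaults: 30 PSBs from the 7/22 mixture, 4 prophages
    whose designed HI_min sits well clear of both thresholds."""
    rng = np.random.default_rng(seed)
    low = tuple(np.round(np.clip(rng.normal(7.0, 1.0, 15), 4.0, 11.0), 2))
    high = tuple(np.round(np.clip(rng.normal(22.0, 2.0, 15), 17.0, 28.0), 2))
    prophages = (
        (6000, 4.0, "SdP"),
        (6000, 5.5, "SdP"),
        (6000, 24.0, "SiP"),
        (6000, 26.0, "SiP"),
    )
    return FixtureSpec(
        seed=seed, low_hi_targets=low, high_hi_targets=high, prophages=prophages
    )


@dataclass
class FixtureTruth:
    lexa_interval: tuple[int, int] | None
    csb_interval: tuple[int, int] | None
    psb_intervals: list[tuple[int, int, float]]
    prophages: list[dict]

    def to_json(self) -> str:
        return json.dumps(
            {
                "lexa_interval": self.lexa_interval,
                "csb_interval": self.csb_interval,
                "psb_intervals": [list(t) for t in self.psb_intervals],
                "prophages": self.prophages,
            },
            indent=2,
        )


def max_design_hi(matrix: SosBoxMatrix) -> float:
    """Largest HI reachable while keeping the core positions fixed."""
    core = {pos for pos, _ in matrix.core_positions}
    pen = matrix.penalties
    return float(
        sum(pen[i].max() for i in range(matrix.motif_length) if i not in core)
    )


def _has_internal_extra_core(seq: str) -> bool:
    """True when a 20-mer contains a core pattern other than its own (offset 2)."""
    return any(m.start() != 2 for m in CORE_PATTERN.finditer(seq))


def design_sequence_for_hi(
    matrix: SosBoxMatrix,
    target_hi: float,
    tolerance: float = 0.25,
    seed: int = 0,
) -> str:
    """Core-preserving 20-mer whose HI is within ``tolerance`` of ``target_hi``.

    Random-restart coordinate descent from the consensus: each attempt starts
    from the consensus with a few seeded random non-core substitutions, then
    repeatedly adopts the single substitution bringing the score closest to
    the target, rejecting candidates that would embed a second core pattern
    inside the motif.  Deterministic given the seed.
    """
    if target_hi < 0:
        raise FixtureError(f"negative HI target {target_hi}")
    reachable = max_design_hi(matrix)
    if target_hi > reachable + tolerance:
        raise FixtureError(
            f"HI target {target_hi} exceeds maximum {reachable:.2f} with core fixed"
        )
    rng = np.random.default_rng(seed)
    core = {pos for pos, _ in matrix.core_positions}
    pen = matrix.penalties
    positions = [i for i in range(matrix.motif_length) if i not in core]
    best_seq: str | None = None
    best_gap = float("inf")
    for attempt in range(30):
        seq = list(matrix.consensus)
        for i in rng.choice(positions, size=min(attempt, len(positions)), replace=False):
            seq[int(i)] = BASES[int(rng.integers(4))]
        if _has_internal_extra_core("".join(seq)):
            continue
        current = hi_score(matrix, "".join(seq))
        for _ in range(100):
            move: tuple[float, float, int, str] | None = None
            for i in positions:
                base_now = seq[i]
                for b in BASES:
                    if b == base_now:
                        continue
                    cand_hi = (
                        current
                        - pen[i, BASES.index(base_now)]
                        + pen[i, BASES.index(b)]
                    )
                    gap = abs(cand_hi - target_hi)
                    if move is None or gap < move[0] - 1e-12:
                        cand = seq.copy()
                        cand[i] = b
                        if _has_internal_extra_core("".join(cand)):
                            continue
                        move = (gap, cand_hi, i, b)
            if move is None or move[0] >= abs(current - target_hi) - 1e-12:
                break
            _, current, i, b = move
            seq[i] = b
        gap = abs(current - target_hi)
        if gap < best_gap:
            best_gap, best_seq = gap, "".join(seq)
        if best_gap <= tolerance:
            break
    assert best_seq is not None
    achieved = hi_score(matrix, best_seq)
    if abs(achieved - target_hi) > tolerance:
        raise FixtureError(
            f"could not reach HI {target_hi} (best {achieved:.3f}) "
            f"within tolerance {tolerance}"
        )
    return best_seq


def _backtranslate(protein: str) -> str:
    return "".join(_CODON_FOR_AA[aa] for aa in protein) + "TAA"


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list(BASES), size=length, p=p))


def _scrub_cores(
    seq: list[str], protected: list[tuple[int, int]], rng: np.random.Generator
) -> None:
    """Mutate away every CTG-N10-CAG occurrence not belonging to a planted box.

    For each offending occurrence one core base lying outside all protected
    intervals is substituted.  Iterates until clean; planted boxes are
    guaranteed untouched.
    """
    def in_protected(pos: int) -> bool:
        return any(lo <= pos < hi for lo, hi in protected)

    planted_pattern_starts = {lo + 2 for lo, _ in protected}
    for _ in range(50):
        text = "".join(seq)
        dirty = False
        for m in CORE_PATTERN.finditer(text):
            s = m.start()
            if s in planted_pattern_starts:
                continue
            core_bases = [s, s + 1, s + 2, s + 13, s + 14, s + 15]
            editable = [p for p in core_bases if not in_protected(p)]
            if not editable:
                raise FixtureError(
                    f"unremovable core pattern at {s} inside protected region"
                )
            p = editable[int(rng.integers(len(editable)))]
            choices = [b for b in BASES if b != seq[p]]
            seq[p] = choices[int(rng.integers(len(choices)))]
            dirty = True
        if not dirty:
            return
    raise FixtureError("core scrubbing did not converge")


_LEXA_SLOT = 2000
_BG_START = 4000
_BG_STRIDE = 1200
_BG_CDS_LEN = 600
_PP_CDS_OFFSETS = (500, 1500, 2500)


def generate_fixture(
    spec: FixtureSpec,
    outdir: str | Path | None = None,
    matrix: SosBoxMatrix | None = None,
) -> tuple[GenomeRecord, list[ProphageRegion], FixtureTruth, dict[str, Path]]:
    """Build the synthetic replicon; optionally write GenBank + BED + truth JSON.

    Returns ``(genome, prophage_regions, truth, paths)`` where ``paths`` is
    empty when ``outdir`` is None.  Raises :class:`FixtureError` when the
    features do not fit the replicon or an HI target is unreachable.
    """
    matrix = matrix or default_matrix()
    L = matrix.motif_length
    rng = np.random.default_rng(spec.seed)
    targets = list(spec.low_hi_targets) + list(spec.high_hi_targets)
    if len(targets) > spec.n_background_cds:
        raise FixtureError(
            f"{len(targets)} HI targets but only {spec.n_background_cds} "
            "background CDS promoters to host them"
        )

    host_end = _BG_START + _BG_STRIDE * spec.n_background_cds
    pp_start = host_end + 600
    needed = pp_start + sum(length for length, _, _ in spec.prophages) + 200
    n = spec.replicon_length or needed
    if n < needed:
        raise FixtureError(f"replicon_length {n} < required {needed}")

    seq = _random_sequence(rng, n, spec.gc_background)
    cds_list: list[CdsFeature] = []
    protected: list[tuple[int, int]] = []
    psb_truth: list[tuple[int, int, float]] = []
    lexa_interval = csb_interval = None

    if spec.plant_lexa:
        references = load_lexa_references()
        lexa_prot = next(iter(references.values()))
        lexa_dna = _backtranslate(lexa_prot)
        lexa_interval = (_LEXA_SLOT, _LEXA_SLOT + len(lexa_dna))
        seq[lexa_interval[0] : lexa_interval[1]] = list(lexa_dna)
        cds_list.append(
            CdsFeature(
                "lexA", *lexa_interval, "+",
                product="LexA repressor", translation=lexa_prot,
            )
        )
        if spec.plant_csb:
            csb_interval = (_LEXA_SLOT - 100, _LEXA_SLOT - 100 + L)
            seq[csb_interval[0] : csb_interval[1]] = list(matrix.consensus)
            protected.append(csb_interval)

    # background CDSs on alternating strands, one designed PSB per promoter
    for i in range(spec.n_background_cds):
        start = _BG_START + _BG_STRIDE * i
        end = start + _BG_CDS_LEN
        strand = "+" if i % 2 == 0 else "-"
        cds_list.append(CdsFeature(f"bg_{i:03d}", start, end, strand))
        if i < len(targets):
            box = design_sequence_for_hi(
                matrix, targets[i], spec.design_tolerance,
                seed=int(rng.integers(2**31)),
            )
            box_start = start - 100 if strand == "+" else end + 80
            seq[box_start : box_start + L] = list(box)
            protected.append((box_start, box_start + L))
            psb_truth.append((box_start, box_start + L, float(targets[i])))

    # prophage regions, each with three CDSs; the designed box (if any) sits
    # in the first CDS's promoter and determines HI_min
    regions: list[ProphageRegion] = []
    pp_truth: list[dict] = []
    cursor = pp_start
    for j, (length, designed, label) in enumerate(spec.prophages):
        if min(_PP_CDS_OFFSETS) < 300 or max(_PP_CDS_OFFSETS) + _BG_CDS_LEN > length:
            raise FixtureError(f"prophage {j} too short for its CDS layout")
        pid = f"pp_{j:03d}"
        region = ProphageRegion(pid, "synthetic_1", cursor, cursor + length)
        regions.append(region)
        for m, off in enumerate(_PP_CDS_OFFSETS):
            cds_list.append(
                CdsFeature(f"{pid}_cds{m}", cursor + off, cursor + off + _BG_CDS_LEN, "+")
            )
        if designed is not None:
            box = design_sequence_for_hi(
                matrix, designed, spec.design_tolerance,
                seed=int(rng.integers(2**31)),
            )
            box_start = cursor + _PP_CDS_OFFSETS[0] - 100
            seq[box_start : box_start + L] = list(box)
            protected.append((box_start, box_start + L))
            psb_truth.append((box_start, box_start + L, float(designed)))
        pp_truth.append(
            {
                "prophage_id": pid,
                "interval": [cursor, cursor + length],
                "designed_hi_min": designed,
                "truth_label": label,
            }
        )
        cursor += length

    _scrub_cores(seq, protected, rng)
    genome = GenomeRecord("synthetic_1", "".join(seq), cds_list)
    _verify_planting(genome, matrix, protected, psb_truth, csb_interval, spec)
    truth = FixtureTruth(lexa_interval, csb_interval, psb_truth, pp_truth)

    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths["genome"] = outdir / "fixture.gbk"
        paths["prophages"] = outdir / "prophages.bed"
        paths["truth"] = outdir / "truth.json"
        write_genome(genome, paths["genome"])
        write_prophage_bed(regions, paths["prophages"])
        paths["truth"].write_text(truth.to_json() + "\n")
    return genome, regions, truth, paths


def _verify_planting(
    genome: GenomeRecord,
    matrix: SosBoxMatrix,
    protected: list[tuple[int, int]],
    psb_truth: list[tuple[int, int, float]],
    csb_interval: tuple[int, int] | None,
    spec: FixtureSpec,
) -> None:
    from .sosbox_scoring import scan_region

    hits = {(h.start, h.end): h.hi for h in scan_region(matrix, genome)}
    expected = set((lo, hi) for lo, hi in protected)
    if set(hits) != expected:
        raise FixtureError(
            f"planted intervals {sorted(expected)} != scanned {sorted(hits)}"
        )
    for lo, hi, target in psb_truth:
        got = hits[(lo, hi)]
        if abs(got - target) > spec.design_tolerance + 1e-9:
            raise FixtureError(
                f"planted box at {lo} scores {got:.3f}, designed {target}"
            )
    if csb_interval is not None and abs(hits[csb_interval]) > 1e-9:
        raise FixtureError("planted consensus CSB does not score 0")
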
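# Methods

## Model

LexA binding potential of a 20-bp window *w* is scored by the Heterology
Index under a position count matrix `n(i, b)`:

```
HI(w) = Σ_{i=0..19} ln[ (n(i, c_i) + p) / (n(i, w_i) + p) ],   p = 0.5
```

with `c` the per-column-argmax consensus. HI is non-negative, zero exactly
when every position carries a count-maximal base, and additive over
positions. The pseudocount keeps never-observed bases finite and is
configurable; 0.5 is the classical choice for this statistic.

A window is a *potential SOS box* (PSB) when it matches the invariant
palindromic core of the canonical operator — CTG at motif positions 3–5 and
CAG at 16–18 (1-based) — with a configurable mismatch allowance (default 0).
Scanning covers both strands; because the core maps onto itself under
reverse complement, each genomic interval is evaluated in both orientations
and reported once, keeping the lower-HI orientation (ties keep the plus
strand). Windows containing N are skipped.

### Packaged matrix

The default matrix is built from 14 experimentally characterized *E. coli*
K-12 LexA operators (recA, sulA, umuDC, uvrA, uvrB, uvrD, the two lexA
operators, recN, dinI, polB, sbmC, dinB, ruvAB) written as core-aligned
20-mers, then **palindromically symmetrized**: `counts[i][b] +=
counts[L-1-i][complement(b)]`. Symmetrization pools the two strands of each
double-stranded site, makes HI strictly strand-symmetric (a physical
requirement for a palindromic operator), and yields exactly the canonical
consensus TACTG(TA)₅CAGTA. The matrix ships as a documented TSV
(`sosdep/data/sosbox_matrix_ecoli.tsv`) and is user-replaceable; the
consensus is always recomputed from counts on load, never trusted from the
file.

## Host profiling

1. **LexA detection** — local protein alignment (BLOSUM62, gap open −11 /
   extend −1) of every CDS translation against a packaged *E. coli* LexA
   reference (UniProt P0A7C2), score normalized by reference length.
   Default threshold 1.5 (half-bits per reference residue): the self-match
   scores ≈ 5.0, recognizable orthologs score well above the threshold, and
   unrelated proteins score ≈ 0.2–0.5. An optional profile-HMM mode via
   pyhmmer is supported when the user supplies a LexA family profile; none
   is packaged, keeping the default path download-free. Ties break to the
   lowest start coordinate.
2. **CSB confirmation** — the *lexA* promoter window (defaults below) is
   scanned; the lowest-HI hit confirms a canonical SOS box if
   HI ≤ `csb_cutoff` (default 12.0). The cutoff only gates CSB presence; it
   plays no role in prophage classification.
3. **PSB survey** — whole-replicon scan by default (promoter-restricted
   scope is available); the HI values of all deduplicated hits form the
   clustering input.
4. **Thresholds** — the 1-D HI values are clustered (values sorted first,
   so input order can never matter). Default method is Mean Shift with a
   Silverman rule-of-thumb bandwidth `0.9 · min(sd, IQR/1.34) · n^(−1/5)`;
   `kmeans2` (k = 2, deterministic percentile initialization) and `otsu`
   are available as baselines. HI_C1 = max(low cluster), HI_C2 = min(high
   cluster), and HI_C1 < HI_C2 is required — otherwise the genome is
   AMBIGUOUS_CLUSTERING. At least `min_psb_count` = 10 PSBs are required
   before clustering is attempted; thresholds are always derived per genome
   and never pooled across genomes, since HI distributions differ
   significantly even between closely related species.

### Cluster-to-threshold mapping

Mean Shift on small samples can split off tiny satellite clusters at the
extremes — most visibly the genome's own near-consensus operators (the CSB
scores exactly 0), which can sit a bandwidth away from the bulk of the low
component. Taking the literal smallest-mean cluster would then collapse
HI_C1 onto the satellite and absurdly classify only near-consensus
operators as binding. The mapping therefore anchors the low and high
clusters at the **two most populous clusters** (ordered by mean) and merges
minor clusters lying below/above that pair into the nearest extreme; a
value below every member of the low cluster is unambiguously on the binding
side. Clusters strictly between the dominant pair belong to neither — their
members fall into the SuP gap. On clean two-component data this reduces to
the plain smallest/largest-mean rule, and the resulting partition is
verified against an independent KDE-valley oracle in the test suite.

## Prophage classification

Promoter windows are taken for every CDS overlapping the prophage region:
300 bp upstream of the translation start plus 50 bp into the CDS, on the
CDS strand, truncated at replicon ends (a `--circular` mode wraps instead).
The 300/50 default is a deliberate, configurable choice — generous enough
to contain operators near any plausible transcription start; windows of
neighboring CDSs are not merged and are not clipped at adjacent genes.
HI_min is the minimum over all deduplicated hits in those windows.

Classification: `HI_min ≤ HI_C1 → SdP`, `HI_min ≥ HI_C2 → SiP`, strictly
between → SuP. Both boundaries are inclusive because the thresholds are
cluster extrema: a value equal to max(low cluster) *is* a member of the low
cluster. A prophage whose promoters contain no PSB at all is called SiP
with an explicit `no_psb` flag — under the model, LexA repression is
impossible without a candidate operator — rather than SuP; the flag
preserves auditability of that policy. Prophages on hosts whose profile is
not OK are emitted with class `NA` and the host status.

Summaries report class counts and percentages (two decimals, half-up
rounding). Validation against experimental truth uses standard
sensitivity/specificity/accuracy with Clopper–Pearson exact intervals
(chosen because small wet-lab truth sets make normal approximations
unreliable; at k = n the lower bound has the closed form (α/2)^(1/n)).
Predicted SuP against a binary truth counts as an error by default
(`exclude` is available).

## Synthetic data generator

`synthetic_fixtures` builds fully annotated replicons with exact truth:

* background sequence at configurable GC (default 0.50), **scrubbed** of
  every accidental CTG-N₁₀-CAG core so the only PSBs are planted ones;
* a *lexA* CDS (back-translated packaged reference protein) with the
  consensus CSB ending 80 bp upstream of its start;
* 30 background CDSs on alternating strands whose promoters carry operators
  designed to HI targets drawn from the low ~ N(7, 1) / high ~ N(22, 2)
  mixture (15 + 15 by default), mirroring the bimodal *E. coli*
  distribution with modes near 7 and 22;
* four prophage regions (three CDSs each) by default, with promoter
  operators designed to HI_min 4.0 / 5.5 (SdP side) and 24.0 / 26.0 (SiP
  side) — each well clear of where the thresholds land;
* operator design by random-restart coordinate descent over non-core
  positions (tolerance 0.25), rejecting candidates that would embed a
  second core pattern; every planted box is re-scanned after assembly and
  the build fails if any interval or score deviates.

Outputs (GenBank + BED + truth JSON) are byte-stable functions of the seed.

What the generator does **not** emulate: realistic phage gene content and
architecture, operator-context effects (spacing to promoters, sigma-factor
sites), horizontal-transfer compositional gradients, assembly gaps/Ns, and
the long low-HI tail a real regulon produces. Passing the planted-truth
suite therefore demonstrates that the pipeline's machinery is correct and
self-consistent, not that the packaged matrix and thresholds transfer to
any particular real genome — for real-genome claims the CLI must be run on
real data.

## Numerical choices and degenerate inputs

* Internal coordinates are 0-based half-open; all reports are 1-based
  inclusive and say so in a header comment.
* Strand-orientation ties in the scanner are resolved at 1e-9 (the
  symmetrized matrix makes the two orientations exactly equal up to
  floating-point summation order).
* Intervals shorter than the motif scan to empty rather than erroring;
  empty CDS lists yield empty promoter sets; an empty call set summarizes
  to zero counts with an `empty_flag`.
* Problem sizes in the test and acceptance runs (20 fixtures of ~65 kb, 50–
  100 5-kb oracle sequences, 200-point mixtures) were chosen as the
  smallest scales at which every statistical behavior under test is
  unambiguous.

## Known limitations

* Detection covers only LexA-type regulation with a CTG/CAG-core operator;
  taxa using unrelated repressor families (or none) come out NO_LEXA /
  NO_CSB by design.
* The packaged matrix is *E. coli*-derived; for distant taxa a
  user-supplied matrix is scientifically preferable and fully supported.
* Multi-replicon inputs are profiled on the largest replicon; plasmid-borne
  prophages are classified against the chromosomal thresholds.
* Prophage boundaries must be supplied; the package neither predicts nor
  refines them, and does no gene calling.
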
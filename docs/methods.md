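# Methods

## The biological model

HNWD genes (*het-d*, *het-e*, *het-r* and relatives in *Podospora
anserina*) encode NLRs whose C-terminal sensor domain is a tandem array of
WD40 repeats, each 126 bp / 42 aa. Within a gene the repeats are nearly
identical (>80–100% amino-acid identity, "high internal conservation"),
kept homogeneous by concerted evolution via unequal crossover, which also
changes repeat number. Seven positions per repeat — 10, 11, 12, 14, 30, 32
and 39 — are hypervariable under diversifying selection and sit at the
predicted ligand-interaction surface. A repeat *variant* is a distinct
combination of amino acids at these seven positions; an allele's
architecture ("barcode") is its ordered list of variants. Reactive
*het-e* alleles have 10–12 repeats, reactive *het-d* alleles exactly 11;
stop codons or frameshifts anywhere in the array break the protein.
Crucially, a correct repeat count is necessary but not sufficient for
reactivity — one known 11-repeat *het-e* allele triggers no reaction with
the common *het-c* alleles — so this package's "candidate" verdict is
deliberately only a necessary-conditions screen.

The canonical repeat used as the default consensus is
`TGTQTLEGHGGSVWSVAFSPDGQRVASGSDDKTIKIWDAASG` (the second HIC repeat of a
known *E2* allele); its 7-position signature is `GGSWDKA`.

## Synthetic data generator

The simulator emulates the structure of real HNWD haplotypes rather than
their full evolutionary history: a gene is 5' flank + N tandem repeats +
3' flank. Defaults: 500-nt uniform-random flanks (GC 50%, non-repetitive
is all that matters), repeat counts uniform on 6–12 (bracketing the
natural range around the functional 10–12), variant signatures sampled
without replacement from the product space of the 20-aa alphabet over the
seven positions (entry 1 is always the consensus signature), and
`background_sub_rate` point substitutions per nucleotide outside the
hypervariable codons (0 by default; 0.01/site in robustness tests,
consistent with the >80% identity floor). Reverse translation uses the
lexicographically first codon per amino acid so nucleotide-level truth is
deterministic; background substitutions never create stops, because
disruptions are planted explicitly:

- *unequal crossover*: duplication inserts an exact tandem copy of a
  contiguous repeat block after itself; deletion removes the block —
  mirroring how natural length polymorphism arises;
- *stop*: one sense codon outside the hypervariable codons becomes
  TAA/TAG/TGA (seeded choice), leaving the variant signature intact so
  classification truth survives the disruption;
- *frameshift*: one seeded bp deleted inside a repeat.

All randomness derives from one root seed via named substreams
(`numpy.random.default_rng([seed, crc32(stream)])`), so identical configs
give byte-identical FASTA/TSV output. What the generator does **not**
emulate: sequencing error profiles, assembly artifacts (chimeric repeats,
N-tracks), inter-paralogue repeat exchange, introns, and the divergent
"cryptic" repeats at the domain's C-terminus. Passing tests therefore
demonstrate correctness of the algorithms on structurally faithful input,
not robustness to raw long-read assembly noise.

## Repeat detection

Pass 1 translates every forward reading frame and slides a 42-aa window;
a window is accepted when its mismatches to the consensus **at the 35
non-hypervariable positions** number ≤ 6 (an ~83% identity floor; the
hypervariable positions are free because variation there is the signal,
not noise). Accepted windows are chained greedily left-to-right into
non-overlapping hits (ties: leftmost start, then fewest mismatches, then
lexicographically smaller window). Forward-only by default since inputs
are oriented haplotypes; a flag enables reverse-complement scanning.

Pass 2 rescues disrupted units that cannot pass an amino-acid filter: in
every inter-hit gap of 0.5–1.5 repeat periods, and in windows of 1.5
periods flanking the outermost hits, each Pass-1 hit's nucleotide
sequence and the reverse-translated consensus are aligned (edlib,
infix mode) with the hypervariable codons masked to N, so the edit budget
(≤ 8) counts only conserved-position mismatches and indels. A rescued
unit is flagged `frameshift_suspect` if its length ≢ 0 mod 3 or the
alignment contains an indel, and `has_stop` if its best-frame translation
contains a stop. Masking is what keeps the budget meaningful: an
unmasked disrupted unit can legitimately differ from every template at
all seven hypervariable codons.

Known positional ambiguity: a 1-bp deletion within the last codons of a
repeat leaves that unit's window acceptable and shifts the frame break
into the next unit, so the flag may land one unit downstream of the
planted position. Per-allele sensitivity (exactly one flagged unit per
planted disruption) is the contract; flag position is exact except at
unit boundaries.

Coordinates are 0-based half-open internally and 1-based inclusive in all
written reports.

## Classification and dissimilarity

Signatures are the residues at the seven positions (X where a partial
repeat ends early). Variant IDs are assigned per family in
first-appearance order starting at 1 — the IDs are arbitrary labels, and
persisting the catalog is what makes them reproducible across runs.
Per-position composition is summarized as a 42×21 count matrix with
information content log2(20) − entropy in bits (log2 20 ≈ 4.32 at a
fully conserved position).

Variant dissimilarity is the sum over the seven positions of an
amino-acid physicochemical distance. The packaged default is the
Grantham (1974) table **recomputed from the original composition,
polarity and molecular-volume properties**
(d = ρ·sqrt(1.833·Δc² + 0.1018·Δp² + 0.000399·Δv²), ρ scaled so the
mean over the 190 pairs is 100, rounded to integers). This reproduces
the published table exactly for most pairs and within ±1 for a handful
where the original printing rounded differently; tests assert published
reference values at ±1. Any 20×20 symmetric zero-diagonal TSV can be
substituted. Positions involving X contribute the matrix's mean
off-diagonal value — an unbiased placeholder preferred over 0
(understates) or the maximum (overstates). The distance is a pre-metric;
the triangle inequality is not asserted because arbitrary published
tables need not satisfy it.

## Palette generation

Colours live in CIE L\*a\*b\*, chosen for approximate perceptual
uniformity; perceptual distance is Euclidean Lab distance (ΔE*ab), which
keeps the objective simple and oracle-checkable. The objective is
**nonmetric**: only the rank order of the physicochemical distances must
be preserved, scored by Kruskal stress-1 with the monotone disparities
fitted by isotonic regression (pool-adjacent-violators; the
implementation delegates to scikit-learn and is tested against an
independent hand-written PAVA to 1e-9).

Optimization is simulated annealing with random restarts (default 8
restarts × 600 iterations; geometric cooling of both the proposal scale,
30 → 2 ΔE, and the temperature, 5e-2 → 1e-4). Proposals outside the sRGB
gamut or the lightness bounds are rejected outright, so feasibility is
maintained by construction, and the best configuration ever visited is
returned — hence achieved stress never exceeds the best random start.
Lightness is bounded to [35, 90] so variant numbers stay legible on
white figures and **pure black remains reserved for disrupted repeats**.
Gamut membership means every linear RGB channel in [−tol, 1+tol]; the
reference white is derived from the sRGB primary matrix itself so the
Lab→sRGB→Lab round trip is exact at the white point and within 1/255 per
channel across the 24-bit cube. Ties between equally stressed restarts
go to the lowest restart index; all randomness comes from the config
seed, so identical inputs give identical hex lists.

## Architecture comparison and screening

Barcode comparison is unit-cost Levenshtein over the variant-ID
alphabet, computed by suffix dynamic programming so the backtrace emits
the leftmost optimal script, preferring substitutions, then deletions.
A weighted-substitution mode is not implemented beyond unit cost;
ranking beyond distance is qualitative by design. Disrupted repeats keep
their variant ID in the barcode (figures still draw them, in black) but
force the screen verdict. Architectures spanning scaffold breaks refuse
comparison unless forced, since repeat order across a break is
unverified. Panel assignment inherits a phenotype **only** at distance
0; near misses are reported as ranked "similar to" calls with edit
scripts, because no similarity threshold for phenotype transfer is
defensible. Screen rules are configurable per family; defaults are
*het-e* ≥ 10 repeats and *het-d* exactly 11.

## Numerical and design choices

- Detection mismatch budget 6/35 non-hypervariable positions ≈ 83%
  identity floor; uniform across positions (whether the conserved GH/WD
  motif cores should be stricter is unknown, so no extra weighting).
- Rescue gap window [0.5, 1.5] periods; edit budget 8 on masked
  templates; terminal windows 1.5 periods.
- Partial terminal repeats are flagged `partial` and excluded from
  barcodes by default.
- Stress denominator uses embedded distances (Kruskal's stress-1); a
  degenerate all-coincident configuration returns stress 1 unless the
  targets are constant.
- Pipeline problem sizes in tests: 20 seeds × 10 alleles for recovery,
  100 alleles for the disruption screen, 50 matrices × 8 variants for
  palette benchmarking, annealing shortened to 2 restarts × 150
  iterations where only relative quality is at stake — sizes chosen to
  make the statistical claims at desk scale.

## Limitations

- Detection assumes one tandem array per input haplotype; it is not a
  whole-genome gene finder, and paralogue discrimination is the caller's
  job via the consensus choice.
- The regex formulation used in earlier literature is replaced by an
  explicit consensus-mismatch matcher; sensitivities are equivalent on
  conforming repeats but not formally identical.
- The Grantham recomputation's ±1 rounding differences are irrelevant at
  signature-sum scale but mean single cells may differ from specific
  printings of the table.
- Palette quality is stochastic: stress is near 0 for ≤ 7 variants in
  3-D but grows with variant count; the guarantee is seeded
  reproducibility and improvement over random assignment, not global
  optimality.
- The functionality screen encodes necessary conditions from classical
  genetics; it cannot predict reactivity, and does not try to.
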
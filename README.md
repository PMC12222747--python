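# hicrepeats

Analysis of **highly internally conserved (HIC) WD40 tandem repeats** in the
sensor domains of fungal NOD-like receptors (NLRs), built for the *het-d* /
*het-e* / *het-r* ("HNWD") incompatibility genes of *Podospora anserina* and
genes like them.

These NLRs detect non-self through a C-terminal WD40 domain made of tandem
126-bp (42-aa) repeats that are 80–100% identical to each other within a
gene — homogenized by concerted evolution through unequal crossover — while
seven codon positions per repeat (10, 11, 12, 14, 30, 32, 39) are
hypervariable and under diversifying selection. The ordered sequence of
repeat *variants* (distinct 7-aa combinations at those positions) forms an
allele's "barcode", and the barcode, not just the repeat count, determines
recognition specificity. This package provides the computational toolchain
for working with such domains:

- **`simulate`** — seeded generator of HNWD-like genes with known planted
  barcodes, unequal-crossover duplications/deletions, stop codons and
  frameshifting 1-bp deletions, for validating every downstream stage.
- **`detect`** — two-pass repeat detection: a consensus window scan over all
  reading frames (mismatch budget confined to the 35 non-hypervariable
  positions), then nucleotide-level rescue of disrupted units in the gaps.
- **`catalog`** — 7-aa signature extraction, stable per-family variant IDs,
  and position-frequency/logo statistics.
- **`dissimilarity`** — variant distance = Σ over the seven positions of the
  Grantham (1974) physicochemical amino-acid distance (swappable table);
  repeat Hamming distance; one-hot nucleotide encoding for repeat-space PCA.
- **`palette`** — nonmetric MDS of variants into CIE L\*a\*b\* colour space
  (Kruskal stress-1, simulated annealing, sRGB-gamut constrained), so
  physicochemically similar variants get perceptually similar colours.
- **`alleles`** — barcode comparison by unit-cost edit distance with edit
  scripts, assignment against a reference allele panel, and the
  functionality screen (≥10 repeats for *het-e*, exactly 11 for *het-d*,
  no disruptions).
- **`viz`** — publication-style SVG block diagrams of repeat architectures
  (disrupted repeats black, labels contrast-checked).
- **`pipeline`** — one-seed, one-config orchestration of all stages with a
  reproducibility manifest.

## Worked example

Classify and colour a set of repeat variants (`examples/03`):

```python
from hicrepeats.catalog import VariantCatalog
from hicrepeats.dissimilarity import distance_matrix, grantham_matrix
from hicrepeats.palette import PaletteConfig, fit_palette

catalog = VariantCatalog(family_id="het-e")
for sig in ["GGSWDKA", "GGSWDKV", "GGSWDRA", "AKCWDKA", "GGSYEKA", "TTSWDKA"]:
    catalog.get_or_assign(sig)

D = distance_matrix(catalog, grantham_matrix())
pal = fit_palette(D, PaletteConfig(seed=42, n_restarts=4, iterations=400))
```

prints (abridged):

```
variants 1 vs 2 differ only at the last position (A/V): distance 65 = Grantham(A,V)

fitted palette (Kruskal stress-1 = 0.0000):
  variant 1: #B47EAB  (L*=60, a*=29, b*=-16)
  variant 2: #F37CB4  (L*=67, a*=52, b*=-9)
  ...
```

`GGSWDKA` is the signature of the canonical *het-e* repeat
(`TGTQTLEGHGGSVWSVAFSPDGQRVASGSDDKTIKIWDAASG`, positions
10,11,12,14,30,32,39). Variant 2 differs from it by a single A→V at
position 39, so their distance is exactly one Grantham cell (65), and the
zero stress means the fitted colour distances perfectly preserve the rank
order of the physicochemical distances — variants 1 and 2 come out as
neighbouring pinks while the distant variant 4 lands in green.

The other scripts in `examples/` walk through simulation, detection +
classification, architecture comparison + screening, and the full pipeline.
A thin CLI mirrors the library (`hicrepeats simulate|detect|classify|
distances|palette|assign|diagram|pipeline`).

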
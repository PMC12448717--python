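# fldqc

Fragment-length-distribution quality control for single-cell ATAC-seq.

## Why

A healthy ATAC-seq library has a periodic fragment length distribution
(FLD): a nucleosome-free peak near 50 bp followed by mono-, di-,
tri-nucleosomal peaks spaced ~200 bp apart — the footprint of Tn5's
steric exclusion around nucleosomes. At bulk resolution analysts judge
this pattern by eye; at single-cell resolution every barcode has its own
sparse FLD and visual inspection does not scale. `fldqc` turns the
pattern into a per-cell scalar that rises roughly linearly with pattern
strength, so one lower cutoff separates high-quality cells.

## The score

For each cell barcode, with fragment length histogram h(x):

1. **Downsample** h multinomially to a common depth `target_n`
   (default 5000), making the score depth-independent.
2. **Convolve** with a single wavelet
   ψ_{a,b}(t) = cos(a(t−b)) · (σ√(2π))⁻¹ · exp(−½(a(t−b))²/σ²),
   a = 2π/150 bp⁻¹, σ = 0.4 — matched smoothing that denoises the FLD
   while preserving its periodic structure.
3. **Call peaks**: up to 5 strict local maxima (x′ᵢ, aᵢ) of the
   convolved signal, ≥ 100 bp apart, by descending amplitude.
4. **Score** against a nucleosomal mask S(x) = Σᵢ N(x; xᵢ, 35 bp) with
   centers {50, 200, 400, 600, 800} bp:

       fld_score = Σᵢ aᵢ · S(x′ᵢ)

Flat or aperiodic FLDs score near zero; strongly periodic cells score
high. Higher = better, single lower cutoff.

The package also computes the standard companion metrics — **mNSC**
(mononucleosomal/nucleosome-free ratio, 147–294 bp over <147 bp),
**TSSe** (mean coverage at TSS ±50 bp over the outer 100 bp flanks of a
±2 kb window), **FRiP** (fraction of fragments in peaks) and **TC**
(total unique fragments) — a reference-free embedding **distance score**
(normalized Levenshtein feature distance to k nearest vs k farthest
embedding neighbours; lower = better), threshold filtering with
reference-coverage bookkeeping, FLD density plots, and a synthetic-data
generator with tunable periodicity strength θ for end-to-end testing.
See `docs/methods.md` for definitions, defaults and assumptions.

## Worked example

Simulate a small library whose six cells sweep periodicity strength
θ = 0 … 1 at 8000 fragments each, then score it:

```bash
fldqc simulate --n-cells 6 --theta 0.9 --depth 8000 \
      --fraction-in-peaks 0.5 --seed 42 --outdir demo
fldqc score --fragments demo/fragments.bed --barcodes demo/barcodes.txt \
      --target-n 5000 --seed 0 --out demo/qc.tsv
```

With θ increasing per cell (via the Python API,
`make_library(6, theta=[0, .2, .4, .6, .8, 1], depth=8000, seed=42)`),
`demo/qc.tsv` reads:

```
barcode     fld_score  n_fragments_used  downsampled  flag
CELL000000   7.92      5000              True
CELL000001   8.90      5000              True
CELL000002  12.57      5000              True
CELL000003  14.60      5000              True
CELL000004  16.21      5000              True
CELL000005  18.71      5000              True
```

The score recovers the planted quality ordering: the pure-noise cell
(θ = 0) scores 7.9, the fully periodic cell (θ = 1) 18.7, and every cell
was downsampled to the common 5000-fragment depth before scoring.
Companion metrics follow the same pattern — mNSC rises from 0.69 to
0.98 across the sweep, FRiP sits at the planted 0.51, TSSe at ~1.0
(uniform placement):

```bash
fldqc metrics --fragments demo/fragments.bed --barcodes demo/barcodes.txt \
      --peaks demo/peaks.bed --tss demo/tss.bed --out demo/metrics.tsv
fldqc filter --table demo/qc.tsv --rule fld_score:10: --out demo/filtered.tsv
# retained	4/6   (the two weakest-pattern cells are removed)
```

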
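# nsiscreen

A tested re-implementation of a live-cell high-content screen for
compound **non-stickiness** — the ability of a fluorescent small
molecule to enter cells and wash out again, rather than bind
non-specifically.  Non-sticky fluorophores clear quickly and are in
demand as tags for imaging intracellular receptors with a high
signal-to-noise ratio.

The screen images a combinatorial library (an R1 x R2 diversity set on
a xanthene-like scaffold; compound "C9" is R1 block C, R2 number 9) on
multiple cell lines at two timepoints: T0 right after compound
incubation and wash, and T1 after a ~60 min clearance window.  Each
cell's flux is quantified individually — nuclear segmentation,
curvilinear tessellation of cell territories, affine registration of
the two timepoints via nuclei centroids — and scored with the
**non-stickiness index**: with fluxes min–max normalized per
compound x cell-line group (F̂ = (F − F_min)/(F_max − F_min + ε)),

```
NSI = ln( (F̂_T1 + μ) / (F̂_T0 + μ) ),      μ = 0.01
```

Negative NSI = the signal cleared = desirable.  Per-line R1 x R2
heatmaps are aggregated across cell lines (mean, median, or
worst-line) and compounds ranked ascending.  A cheminformatics arm
computes physicochemical properties, fingerprint Tanimoto distances, a
classical MDS map of structure space, and structure–phenotype overlap
statistics; a simulated secondary (root-hair-like) screen provides
cross-system correlation and sign co-occurrence checks.

The original raw screen and library structures are not public, so the
package includes a first-class synthetic-data generator: plate images
(TIFF, three channels, two timepoints, stage drift, read noise,
16-bit quantization) with exact per-cell ground truth, drawn from four
flux behavior classes (no entry, membrane-bound, accumulate,
enter-and-leave) and three localizations (nuclear, perinuclear,
diffuse).  Every pipeline stage is validated by parameter recovery
against that truth.  See `docs/methods.md` for the full model.

## Worked example

```bash
python examples/03_mini_screen_ranking.py
```

renders and analyzes a 24-compound, two-cell-line screen in memory
(about 20 s) and prints:

```
top 5 compounds (most negative aggregate NSI = best):
compound_id       nsi  rank
         J2 -2.381367     1
         B2 -1.479148     2
         G2 -1.318989     3
         L2 -1.313526     4
         J1 -1.179786     5

Spearman(estimated NSI, true log-ratio) over 24 compounds: 0.94
```

The ranking lists compounds by aggregate NSI across both lines; J2's
−2.38 means its normalized fluorescence dropped to roughly
exp(−2.38) ≈ 9% of its uptake level after washout — a strongly
non-sticky compound.  The Spearman of 0.94 against the generator's
true clearance log-ratios shows the image-based pipeline recovers the
compound ordering it was built to estimate.  The other example scripts
cover library construction, single-field quantification, secondary
screen agreement, and the structure-activity map.

A thin CLI wraps the same stages:

```bash
nsiscreen simulate --out plates/ --seed 1        # TIFF plates + truth
nsiscreen analyze --in plates/<plate> --library plates/library.smi --out results/
nsiscreen run --out results/ --seed 1            # in-memory end-to-end
nsiscreen cheminfo --library results/library.smi --nsi results/heatmap_aggregate.csv --out chem/
```

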
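# flimpheno

Quantification of time-domain fluorescence lifetime imaging (FLIM) data and
classification of cell metabolic phenotypes from NAD(P)H and FAD
autofluorescence — with both of the field's standard analysis routes
implemented side by side so they can be compared on equal footing.

## The problem

The endogenous coenzymes NAD(P)H and FAD report cellular metabolism without
labels: each exists in free and protein-bound conformations with different
fluorescence lifetimes, so the shape of the per-pixel photon arrival-time
histogram (TCSPC) encodes metabolic state. Two analysis routes dominate:

1. **Biexponential decay fitting.** Each pixel's decay is modeled as

   I(t) = α₁·exp(−t/τ₁) + α₂·exp(−t/τ₂) + C,   α₁ + α₂ = 1,

   convolved with the instrument response function (IRF), fitted per pixel, and
   summarized by the amplitude-weighted mean lifetime τₘ = α₁τ₁ + α₂τ₂.

2. **Phasor analysis.** The fit-free transform to first-harmonic Fourier
   coordinates at the laser repetition frequency (ω = 2πf, 80 MHz here):

   g = ∫ I(t)·cos(ωt) dt / ∫ I(t) dt,   s = ∫ I(t)·sin(ωt) dt / ∫ I(t) dt.

   Mono-exponential decays lie on the universal semicircle
   (g − ½)² + s² = ¼; biexponential mixtures lie on chords inside it.

The fit yields 8 per-cell features (α₁, τ₁, τ₂, τₘ per channel), the phasor 4
(G, S per channel). The phasor is a 2-D projection of the 3-parameter decay
model, so distinct decompositions can share a phasor position — a classifier
trained on phasor coordinates alone can be blind to differences that decay
fitting resolves. This package quantifies that trade-off with cross-validated
random forests on three feature sets (fit-only, phasor-only, combined).

Because real microscope stacks are bulky and rarely deposited, the package
ships a ground-truthed synthetic TCSPC generator (disk cells, phenotype-
specific decay-parameter distributions, periodic IRF convolution, Poisson
photon noise) so every stage is testable end to end.

## Worked example

```python
from flimpheno import (BiexpParams, TimeGrid, make_irf, simulate_decay,
                       phasor_of_biexp, simulate_dataset, matched_phasor_pair)
from flimpheno.fitting import fit_pixel
from flimpheno.ml import compare_feature_sets, make_folds, train_rft_pairwise
from flimpheno.pipeline import extract_feature_table

grid = TimeGrid()                      # 256 channels over 12.5 ns (80 MHz)
irf = make_irf(grid)                   # Gaussian IRF, 0.3 ns FWHM at 1.0 ns
truth = BiexpParams(alpha1=0.7, tau1=0.5, tau2=3.0)

# one bright pixel: simulate, fit back
hist = simulate_decay(truth, irf, photons=50000, grid=grid, seed=1)
fit = fit_pixel(hist, irf, grid)
print(f"fitted: alpha1={fit.params.alpha1:.3f} tau1={fit.params.tau1:.3f} ns "
      f"tau2={fit.params.tau2:.3f} ns tau_m={fit.tau_m:.3f} ns")
p = phasor_of_biexp(truth)
print(f"phasor of truth: g={p.g:.3f} s={p.s:.3f}")

# two phenotypes that SHARE a phasor position but differ in decomposition
specs = matched_phasor_pair()
dataset = simulate_dataset(specs, n_fields_per_phenotype=2, grid=grid, seed=1, irf=irf)
table = extract_feature_table(dataset, irf)   # fits + phasors -> 12 features/cell
y = (table.group == "degenB").to_numpy().astype(int)
folds = make_folds(y, seed=1)
reports = {name: train_rft_pairwise(table, "degenA", "degenB", name, seed=1,
                                    fold_assignment=folds)
           for name in ("decay8", "phasor4")}
res = compare_feature_sets(reports["decay8"], reports["phasor4"], "accuracy")
print(f"decay8 accuracy={reports['decay8'].mean_accuracy:.3f}  "
      f"phasor4 accuracy={reports['phasor4'].mean_accuracy:.3f}  "
      f"paired p={res.p_value:.2e}")
```

Output:

```
fitted: alpha1=0.701 tau1=0.513 ns tau2=2.958 ns tau_m=1.243 ns
phasor of truth: g=0.483 s=0.398
decay8 accuracy=1.000  phasor4 accuracy=0.467  paired p=7.03e-04
```

The single-pixel fit recovers the ground truth (α₁ = 0.7, τ₁ = 0.5 ns,
τ₂ = 3.0 ns, τₘ = 1.25 ns) to a few percent at 50,000 photons. In the
classification block, the two simulated phenotypes were constructed to project
onto the *same* phasor point, so the phasor-only classifier sits at chance
while the decay-fit features separate the classes perfectly — the paired
fold-wise t-test confirms the difference. On strongly shifted phenotype pairs
(`large_shift_pair()`) the two routes instead agree to within a few accuracy
points.

## Command-line pipeline

```
flimpheno simulate --spec phenotypes.yaml --out data/  --seed 1
flimpheno analyze  --in data/  --out maps/
flimpheno classify --features maps/features.csv --out reports/ --seed 1
```

`simulate` writes HDF5 photon stacks, 16-bit TIFF label masks and ground-truth
CSVs; `analyze` writes 32-bit float parameter/phasor maps (TIFF) and the
per-cell feature CSV; `classify` writes classifier reports (JSON), a summary
CSV and ROC/importance/UMAP figures. Every run emits a `manifest.json` with
SHA-256 checksums, and seeded reruns are byte-identical.

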
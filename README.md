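# libsquant

Quantification of heavy metals (Cd, Cu, Pb) in plant material from
laser-induced breakdown spectroscopy (LIBS), with wavelength selection.

LIBS spectra are wide and strongly collinear: thousands of channels,
several emission lines per element, several channels per line, and a
large majority of channels that carry no analytical information. This
package is for chemometricians who want a tested, reproducible pipeline
that (a) selects the informative wavelengths and (b) calibrates
spectra → concentration (mg kg⁻¹) regressions on them, comparing three
selectors and three regressors on a common calibration / validation /
prediction protocol. Because no public dataset of metal-spiked
*Fritillaria* pellets exists, the package also ships a synthetic LIBS
generator with known ground truth (288 samples in 8 dose groups,
200–1000 nm at 0.5 nm, Gaussian analyte lines, matrix decoy lines,
shot-averaged noise) so every stage is testable offline.

## Methods at a glance

* **PLS1 (NIPALS)** — from scratch; mean-centered, no autoscaling;
  coefficient vector b on the original scale; K-fold RMSECV over
  component counts with a parsimony tie-break.
* **CARS** — competitive adaptive reweighted sampling: per run i, a PLS
  fit on a Monte-Carlo row subsample ranks channels by |b|, an
  exponentially decreasing function rᵢ = a·e^(−k·i) (r₁ = 1, r_N = 2/p)
  forces retention of the top ⌈rᵢ·p⌉, weighted resampling competes them,
  and the subset with the lowest RMSECV wins.
* **Random frog (RF)** — a subset-proposal chain; channel importance is
  the selection probability P_j = N_j / N over N iterations.
* **UVE** — uninformative variable elimination: append noise columns,
  jackknife PLS coefficients leave-one-out, score stability
  c_j = mean(b_j)/sd(b_j), keep channels beating the noise cutoff.
* **Regressors** — PLSR (auto components by RMSECV), RBF-SVR
  (standardized channels and response), and GBM (gbdt, num_leaves=31,
  max_depth=−1, learning_rate=0.1, n_estimators=100) with average-gain
  variable importance.
* **Metrics** — RC²/RMSEC, RV²/RMSEV, RP²/RMSEP on a stratified
  60/28/12% split; R² = 1 − SSE/SST.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import libsquant as lq

spectra, conc = lq.generate_dataset(lq.SimConfig(), seed=42)   # 288 x 1601
report = lq.run_experiment(spectra, conc, seed=42)             # 36-cell grid
t = report.table
print(t[(t.element == "Cd")][["model", "selector", "n_variables", "rp2", "rmsep"]])
```

Output (seed 42):

```
model selector  n_variables      rp2     rmsep
 plsr     full         1601 0.854478 13.646608
 plsr     cars          106 0.918952 10.184334
 plsr     frog           60 0.919565 10.145724
 plsr      uve           37 0.945267  8.369213
  svr     full         1601 0.434831 26.893642
  svr     cars          106 0.870935 12.851806
  svr     frog           60 0.886600 12.046682
  svr      uve           37 0.905857 10.976277
  gbm     full         1601 0.915927 10.372602
  gbm     cars          106 0.919783 10.131986
  gbm     frog           60 0.917699 10.262740
  gbm      uve           37 0.921324 10.034151
```

Each row is one grid cell for cadmium: the regressor, the wavelength
selector (`full` = whole spectrum), how many of the 1601 channels it
used, and the prediction-set R² and RMSE in mg kg⁻¹. The pattern is the
point of the study: selectors compress 1601 channels to a few dozen —
clustered around the true Cd emission lines — and every regressor
predicts as well or better on the selected channels than on the full
spectrum (kernel SVR degrades the most when fed all 1601 channels).

The same pipeline runs from the shell, also on your own wide-CSV
spectra:

```bash
libsquant simulate --out runs/demo --seed 42
libsquant run-all  --out runs/demo --seed 42
libsquant select   --spectra runs/demo/spectra.csv \
    --concentrations runs/demo/concentrations.csv \
    --element Cd --selector cars --out runs/demo
```

`run-all` writes `report.csv` (the 36-cell grid), `predictions.csv`,
per-channel selection scores, the split table and a structured log of
all stage seeds.

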
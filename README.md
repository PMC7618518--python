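# nanodomain

Quantitative analysis of cell-surface protein **nanodomains** from
single-molecule localization microscopy (dSTORM), proximity-labeling
proteomics, and bead-calibrated flow cytometry.

RNA-binding proteins such as nucleophosmin (NPM1) can appear on the outer
surface of living cancer cells, where antibody staining shows them
organized into nanoscale clusters of uniform size laid out in a regular,
lattice-like ("tessellated") pattern, embedded in RNA-binding-protein- and
glycoRNA-rich neighborhoods. This package implements the full quantitative
chain needed to characterize such nanodomains, together with a synthetic
ground-truth generator so every stage can be validated end to end:

- **`nanodomain.simulate`** — clustered blinking-emitter fields on a
  jittered lattice with bimodal per-cluster localization counts, camera
  frames with sCMOS pixel defects, and overdispersed (negative binomial)
  spectral-count matrices with planted enriched proteins.
- **`nanodomain.localization`** — the frame-to-localization chain:
  hot/cold pixel correction (8-neighbour, 3% median rule over a
  4,000-frame average), à-trous B-spline wavelet spot detection
  (order 3, scale 2, threshold 1.2 × sd of the first wavelet level),
  least-squares 2D Gaussian fitting, burst merging (30 nm, ≤ 5 off
  frames), cross-correlation drift correction (magnification 5, 5 bins),
  quality filtering (σ ∈ [60, 270] nm, intensity < 37,800 photons,
  uncertainty < 30 nm), and 17.7 nm 2D-histogram reconstruction.
- **`nanodomain.cluster`** — the unbiased cluster pipeline: Ripley's
  H(r) = L(r) − r with L = √(K/π) on three dense analysis areas, the
  *preferential cluster size* argmaxᵣ H(r) averaged and multiplied by a
  fixed **0.45** factor to seed DBSCAN's ε, then per-cluster
  disk-equivalent diameters (4·√((varₓ+var_y)/2)), nearest-neighbour
  centroid distances, localization counts, and an antibody-per-cell
  estimate. Packaged as the scikit-learn style `RipleySeededDBSCAN`.
- **`nanodomain.proteomics`** — spectral-count hit calling for
  antibody-anchored HRP proximity labeling: contaminant/keratin and
  ≥ 2-unique-peptide filters, per-protein enrichment = mean(target
  replicates)/mean(isotype replicates), and the hit rule
  *enrichment ≥ max(2, global capture ratio)*; cross-cell-line
  intersection classes and RBP-fraction reporting (`EnrichmentHitCaller`).
- **`nanodomain.mesf`** — MESF bead standard curves (log–log linear fit)
  converting flow-cytometry MFI to absolute molecules per cell
  (`MESFCalibration`), the orthogonal check on the imaging-based count.

## Worked example

Generate one HL-60-like synthetic field (119 nm clusters, ~315 nm
spacing, bimodal 65/130 localizations per cluster) and run the full
cluster pipeline:

```python
import dataclasses
from nanodomain import (PRESETS, RipleySeededDBSCAN,
                        generate_cluster_field, field_to_localizations)

spec = dataclasses.replace(PRESETS["HL60"], seed=1)
table = field_to_localizations(generate_cluster_field(spec))
est = RipleySeededDBSCAN().fit(table[["x_nm", "y_nm"]].to_numpy())
```

Output (printed from the fitted attributes):

```
localizations        : 98799
preferential sizes   : [85.0, 80.0, 80.0] nm
DBSCAN eps           : 36.75 nm
clusters             : 1024
mean diameter        : 124.8 nm
mean NN distance     : 305.7 nm
noise fraction       : 0.002
antibodies per cell  : 1976
```

The three analysis areas agree closely on the preferential cluster size
(80–85 nm, the radius where H(r) peaks); 0.45 × their mean gives the
36.75 nm DBSCAN radius. The recovered mean diameter (124.8 nm) sits
within 5% of the 119 nm ground truth — the small positive bias is the
10 nm localization noise folded into the cluster spread — and the mean
centre-to-centre distance reproduces the ~305 nm lattice. At the default
calibration of 50 localizations per antibody the field corresponds to
roughly 2,000 bound antibodies per cell.

The same stages are scriptable from the shell:

```sh
nanodomain simulate field --config cfg.yaml --seed 1 --out locs.csv
nanodomain cluster --locs locs.csv --out outdir/
nanodomain hits --counts a.csv --counts b.csv --counts c.csv --out hitdir/
nanodomain mesf --beads beads.csv --samples samples.csv --out quant.csv
nanodomain run-all --config cfg.yaml --out rundir/
```

Every run directory contains the resolved configuration and a
machine-readable `report.json` with all intermediate values (H curves,
preferential sizes, ε, cluster totals, min-points sensitivity sweep).

## Documentation

See `docs/methods.md` for the models, estimators, parameter defaults,
numerical choices, and the limitations of the synthetic data.
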
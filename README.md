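# phenoscape

Phenoscaping analysis of pooled organoid–immune co-culture screens.

When engineered immune cells (e.g. stIL15-γδ T cells) are co-cultured with
patient-derived organoids (PDOs), both sides change: the tumor cells die or
arrest, and the immune cells are themselves immunomodulated. Mass-cytometry
condition screens measure this reciprocally — hundreds of barcoded 3-D
cultures pooled into single runs, tens of markers per cell — and the
analysis problem is to turn millions of single-cell events into
condition-level statements: *how much* did each condition shift each
marker, *which* signaling dependencies were rewired, and *how much* killing
exceeded the baseline.

`phenoscape` implements that analysis as a tested, reusable library and CLI
for computational biologists working with CyTOF screen data (and the
companion scRNA-seq stem-cell readout), exercisable end-to-end on synthetic
data with planted ground truth.

## What it computes

- **Combinatorial debarcoding** — cells are assigned back to their sample
  by ranking rescaled barcode-channel intensities against a k-of-n code
  scheme (9-choose-4 = 126-plex). The *separation* between the k-th and
  (k+1)-th ranked channel rejects doublets and ambiguous events.
- **Signed EMD and x̄EMD** — for marker distribution *P* in a condition and
  *Q* in its matched control, the shift statistic is the exact 1-D
  Wasserstein-1 distance
  `EMD(P, Q) = ∫ |F_P(x) − F_Q(x)| dx`,
  signed by `sign(median(P) − median(Q))`. Averaging |EMD| over all
  measured markers gives x̄EMD, a coordinate sliced Wasserstein summary of
  total immunomodulation.
- **kNN-DREMI and ΔDREMI** — for each ordered PTM pair (x → y), the joint
  density is estimated on a fine grid with a k-nearest-neighbour estimator
  (`ρ̂ ∝ k / (N π r_k²)`), each x-column renormalised to a conditional
  p(y|x), and the mutual information of the uniformly reweighted joint
  reported in bits — so the score reflects the response function, not the
  cell-density landscape. An 11-PTM panel yields 110 ordered pairs;
  ΔDREMI = DREMI(condition) − DREMI(control) per pair quantifies network
  rewiring.
- **Cytotoxicity and cell state** — therapeutic apoptosis =
  cPARP⁺ fraction in co-culture minus the matched monoculture baseline (in
  percentage points); cells classified apoptotic / S / G0 / other by a
  fixed cPARP → IdU → pRB hierarchy; Kendall τ-b for rank correlations of
  x̄EMD with cytotoxicity.
- **Condition embeddings** — PCA and a diffusion-potential embedding
  (adaptive-bandwidth α-decay kernel → Markov matrix → t-step diffusion →
  −log potential → metric MDS) of per-condition signed-EMD or ΔDREMI
  vectors.
- **Stem-cell index** — scRNA-seq QC (UMI / gene / mitochondrial /
  UMI-read-ratio bounds), per-cell normalization to 10,000 counts excluding
  genes above 5% of a cell's total, ln(1+x) transform, per-cell
  proCSC/revCSC program scores against expression-matched control genes,
  and stem index = revCSC − proCSC.
- **Synthetic screens** — generators that plant arcsinh-scale marker
  shifts, sigmoidal PTM dependencies of tunable strength, barcode codes
  with summed-channel doublets, apoptosis/S-phase fractions and
  proCSC/revCSC count programs, recording every planted parameter so that
  each pipeline stage can be validated against recoverable truth.

## Worked example

```python
from phenoscape import (CytometrySimConfig, generate_cytometry_experiment,
                        arcsinh_transform, signed_emd, compute_shift,
                        xbar_emd, knn_dremi)

config = CytometrySimConfig(
    conditions=["mono", "co"],
    cells_per_condition=5000,
    shift_map={("co", "pSTAT5"): 1.2, ("co", "GranzymeB"): 0.8},
    dependency_map={("mono", ("pSTAT3", "pSTAT5")): 0.2,
                    ("co", ("pSTAT3", "pSTAT5")): 0.8},
    seed=0,
)
table, truth = generate_cytometry_experiment(config)
t = arcsinh_transform(table, cofactor=5.0)
co, mono = t.where_condition("co"), t.where_condition("mono")

print("signed EMD pSTAT5:", round(signed_emd(co["pSTAT5"], mono["pSTAT5"]), 3))
print("signed EMD GranzymeB:", round(signed_emd(co["GranzymeB"], mono["GranzymeB"]), 3))
print("xbar EMD:", round(xbar_emd(compute_shift(co, mono)), 3))
print("DREMI co:", round(knn_dremi(co["pSTAT3"], co["pSTAT5"]), 3),
      "mono:", round(knn_dremi(mono["pSTAT3"], mono["pSTAT5"]), 3))
```

prints

```
signed EMD pSTAT5: 1.195
signed EMD GranzymeB: 0.801
xbar EMD: 0.095
DREMI co: 1.496 mono: 0.112
```

The planted arcsinh-scale shifts (1.2 and 0.8) are recovered by the signed
EMD to within sampling error; x̄EMD averages |EMD| over all ~25 measured
markers, so two genuinely shifted markers among many null ones give a small
but positive condition-level score; and the strengthened pSTAT3→pSTAT5
dependency in "co" raises its DREMI by ~1.4 bits over the monoculture.

A full pipeline demo (simulate → debarcode → gate → center → shift →
DREMI → embed) runs from the shell:

```bash
phenoscape demo --out-dir demo --seed 42
phenoscape run demo/config.yaml
```

and writes per-stage TSVs plus a provenance manifest under `demo/run/`.

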
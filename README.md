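# xrfquant

Quantitative image analysis of micro-X-ray-fluorescence (µXRF) elemental
maps of plant rosettes, built for genetic studies of metal accumulation in
hyperaccumulators such as *Noccaea caerulescens*.

µXRF mapping produces one greyscale intensity raster per element (here Zn,
K, Ca, Ni) plus a Compton scatter raster for each plant, all co-registered.
`xrfquant` turns such scans into heritable quantitative traits in three
steps:

1. **Segmentation.** Every pixel is classified as background, petiole,
   leaf margin, vasculature (vein) or interveinal tissue using classical
   morphological image processing: Otsu thresholding of the four metal
   rasters (union → plant mask), a 15×15 morphological opening to split
   blade from petiole, the internal gradient of the blade for a 3-px
   margin band, and a large-aperture Laplacian ridge detector on the
   Compton raster for the veins (a strongly negative threshold for
   primary/secondary vasculature, the skeleton of the weakly negative
   region for tertiary vasculature).

2. **Quantification.** Spatial accumulation is summarised per plant by the
   concentration quotient of each substructure *s* and element:

   CQ_s = ( Σ_{(x,y)∈A_s} P(x,y) / N_s ) / ( Σ_{(x,y)∈A_p} P(x,y) / N_p )

   i.e. the mean intensity in the substructure divided by the whole-plant
   mean. CQ is dimensionless and invariant to the plant's absolute count
   rate; CQ = 1 means no enrichment. Plant size, per-element plant means,
   and pixel-level metal colocalization (Pearson *r* per metal pair per
   plant) complete the trait table.

3. **Heritability.** For a panel of accessions with replicate plants, each
   trait is fitted with the one-way random-intercept model P = µ + G + ε
   by REML, and broad-sense heritability (repeatability) is the variance
   ratio H² = Var(G) / (Var(G) + Var(ε)).

Robustness tooling mirrors the validation logic of the method: random
square "substructures" as a negative control for CQ heritability,
label-noise injection to show CQ's tolerance to segmentation error, and a
four-parameter sensitivity sweep of segmentation quality (per-class
precision / recall / F1 against a fixed set of manually labelled pixels).

A synthetic-data generator renders rosettes (elliptical blades, thin
petioles, bright-vein Compton rasters) with genotype-structured metal
enrichment and known ground truth, so the entire pipeline is testable
without original scans.

## Worked example

```python
import pandas as pd
import xrfquant as xq

# a small synthetic panel: 8 accessions x 3 replicate plants
spec = xq.PanelSpec(n_accessions=8, n_reps=3, seed=42)
plants, manifest = xq.generate_panel(spec)

rows = [xq.plant_traits(b, xq.segment(b)) for b, _ in plants]
table = pd.DataFrame(rows)
print(table.iloc[0][["sample_id", "plant_size",
                     "CQ_Zn_petiole", "CQ_Zn_vein", "CQ_Zn_tissue",
                     "r_Zn_Ni"]])

report = xq.heritability_report(
    table, trait_columns=["CQ_Zn_petiole", "CQ_Zn_vein", "plant_size"])
print(report[["trait", "var_G", "var_e", "H2"]].round(4))
```

prints

```
sample_id        acc001_r1
plant_size            9092
CQ_Zn_petiole     1.307625
CQ_Zn_vein        1.393374
CQ_Zn_tissue      0.669316
r_Zn_Ni           0.611281

        trait       var_G       var_e     H2
CQ_Zn_petiole      0.0051      0.0059 0.4611
   CQ_Zn_vein      0.0093      0.0043 0.6861
   plant_size 962927.6995 176645.8315 0.8450
```

The first plant stores Zn preferentially in petiole and vasculature
(CQ > 1) at the expense of interveinal tissue (CQ 0.67), and its Zn and Ni
maps colocalize (r = 0.61). The H² column gives the fraction of each
trait's variance attributable to accession (genotype); with only 8
accessions the estimates are noisy — study-scale panels (86 accessions)
recover the generator's true H² = 0.8 to within a few points.

The same workflow is available from the shell:

```sh
xrfquant simulate --out-dir panel/ --seed 0
xrfquant run-all --manifest panel/manifest.csv --out-dir results/
xrfquant segment --zn Zn.tif --k K.tif --ca Ca.tif --ni Ni.tif \
    --compton Compton.tif --out-labels labels.tif
```

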
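# npcscreen

An image-based high-content screening pipeline for **pharmacological
chaperones of NPC1**, the lysosomal cholesterol transporter whose
folding-defective mutants (prototypically I1061T) cause Niemann-Pick
disease type C. The mutant, GFP-tagged, is retained in the endoplasmic
reticulum and degraded; a chaperone that rescues folding lets it traffic
to late endosomes/lysosomes. The screen quantifies that relocalization
directly from two-channel field images (NPC1-GFP + Hoechst) — no
immunostaining — and calls hits by multiparameter thresholding.

The package is aimed at screeners and image-analysis folk who want the
whole chain as tested, importable pieces: segmentation of the GFP pattern,
morphological scoring, plate-robust normalization, assay QC, hit calling,
plus the downstream filipin (cholesterol accumulation) and colocalization
readouts — and a synthetic-plate generator with ground truth so every
stage can be validated without any external imaging data.

## The statistics at the core

Per detected NPC1-GFP object the pipeline measures shape; per field it
reports

- **circularity** — mean over objects of `4πA/P²` (1 for a circle; low
  for the branched reticular ER pattern),
- **smallObjRatio** — area fraction of objects below a size threshold
  (high for the punctate LE/L pattern),
- **GFPInt** — summed GFP intensity inside the pattern per cell-area
  pixel (a proxy for mutant-protein level).

Per plate, features are standardized to robust Z scores
`(x − median)/(1.4826·MAD)`; assay quality is the Z′ factor
`1 − 3(σ₊+σ₋)/|μ₊−μ₋|` (> 0.5 = excellent window); hit thresholds are
per-feature medians of a *marginally active* positive-control group, and
a library well is a hit only when it strictly exceeds **all three**
thresholds.

## A worked example

```sh
python examples/simulate_and_score.py
```

renders a one-well vehicle plate (10 cells/field, 3 fields), writes the
TIFFs, reads them back through the standard I/O path and scores the well:

```
well P1/A01 (vehicle, 3 fields)
  circularity     0.041   (ER-like patterns score low)
  smallObjRatio   0.000   (area share of small objects)
  GFPInt          0.0529  (pattern intensity per cell-area px)
  nuclei/field    10.0    (10 cells simulated)
```

A vehicle well shows the ER phenotype: the detected pattern is one large
branched network, so circularity sits near zero and essentially no area
belongs to small objects; all ten simulated nuclei are recovered from the
Hoechst channel. The other scripts in `examples/` walk through assay QC
(`assay_quality.py`), normalization + hit calling (`hit_calling.py`),
filipin quantification (`filipin_quantification.py`) and colocalization
statistics (`colocalization.py`). A thin CLI (`npcscreen simulate /
features / normalize / qc / hits / filipin / coloc`) wraps the same
functions for shell use.

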
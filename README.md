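# renperf

Quantitative renal blood-flow (RBF) mapping from two perfusion-MRI
modalities, with a synthetic phantom generator and the ROI-level
agreement statistics used to compare them. Written for researchers
analysing kidney-perfusion studies (small-animal or clinical) who need
reproducible, scriptable quantification instead of scanner-console or
GUI tooling.

## What it computes

**FAIR-ASL** (pulsed arterial spin labelling, flow-sensitive alternating
inversion recovery). An interleaved series of equilibrium (M0),
slice-selective inversion (ss-IR, control) and global inversion (ns-IR,
tag) images is averaged per preparation; the perfusion-weighted
difference ΔM = ⟨ss-IR⟩ − ⟨ns-IR⟩ is converted to flow pixel by pixel
with the single-compartment model

    f = 6000 · λ · ΔM · exp(TI/T1) / (2 · M0 · TI)   [ml/100 g/min]

with partition coefficient λ = 0.8 ml/g, inversion time TI = 1.2 s and
tissue T1 = 1.14 s by default (transit and exchange delays neglected).

**DCE-MRI** (dynamic contrast-enhanced). After subtracting the mean of
the pre-contrast baseline volumes and truncating to the first pass of
the bolus, tissue curves are deconvolved by the arterial input function
(AIF, sampled in the abdominal aorta):

    C_T(t) = (C_A ⊛ h)(t),   RBF = 6000 · max h(t)

The discrete lower-triangular Toeplitz system is solved by truncated
SVD; the truncation threshold (fraction of the largest singular value)
is the regularisation knob.

**Agreement statistics.** Group means ± SD for healthy and diseased
kidneys, two-sided paired t-tests on healthy-minus-diseased differences,
Bland–Altman limits of agreement, left/right flow ratios and
repeated-measurement summaries. The per-animal RBF tables of the rat
ischaemia-reperfusion study the defaults are calibrated to ship as CSV
fixtures (`renperf.stats.load_table`).

**Synthetic phantoms.** A 2D two-kidney phantom (cortex ring, medullary
core, aortic cross-section) with known ground-truth perfusion is
forward-simulated through both models — the ASL simulation is the exact
algebraic inverse of the quantification formula, so the noise-free chain
round-trips to machine precision, and the DCE simulation uses the same
rectangle-rule discretisation the deconvolution inverts.

## Worked example

```python
import json
from renperf.io import RunConfig
from renperf.pipeline import run_pipeline

report = run_pipeline(RunConfig(out_dir="demo", seed=0, n_volumes=50,
                                threshold_fraction=1e-12))
print(json.dumps({"asl_roi": report["asl_roi"],
                  "dce_roi": report["dce_roi"]}, indent=2, sort_keys=True))
```

prints (noise-free phantom, cortical truths 316 left / 416 right):

```json
{
  "asl_roi": {
    "cortex_left":  {"mean": 316.00000000000165, "n_pixels": 592},
    "cortex_right": {"mean": 416.0000000000009,  "n_pixels": 592}
  },
  "dce_roi": {
    "cortex_left":  {"mean": 315.99999999999363, "n_pixels": 592},
    "cortex_right": {"mean": 415.9999999999948,  "n_pixels": 592}
  }
}
```

Both chains recover the simulated diseased (left, 316 ml/100 g/min) and
healthy (right, 416 ml/100 g/min) cortical flows; with zero noise a
near-zero SVD threshold is appropriate, while noisy in-vivo data use the
0.15 default. The same run writes perfusion maps (NIfTI), the AIF curve
(CSV), the statistics report with Bland–Altman and ratio plots, and a
provenance record to the output directory. `report["stats"]` holds the
table statistics, e.g. for ASL: diseased 316 ± 102 vs healthy
416 ± 124 ml/100 g/min, mean difference 147 ± 47, paired t-test
p = 0.34%.

The same stages are available from the shell:

```sh
renperf simulate --out sim --seed 0
renperf asl-quant --series sim/asl_series.nii.gz --labels sim/asl_labels.csv \
    --roi sim/masks.nii.gz --ti 1.2 --t1 1.14 --lambda 0.8 --out out
renperf dce-quant --series sim/dce_series.nii.gz --roi sim/masks.nii.gz --out out
renperf stats --out out
renperf run --out full_run --seed 0
```

A full-defaults YAML config template ships at
`src/renperf/data/default_config.yaml`.

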
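# retinotort

Retinal vascular tortuosity — how much and how often the blood vessels of
the eye fundus bend — is a candidate biomarker for diabetic retinopathy,
hypertension and other vascular disease.  Because human grading of
tortuosity is subjective and shows substantial inter- and intra-rater
variability, objective measurements need two things at once: reference
tortuosity metrics computed from extracted vessel centerlines, and a
statistical workbench that compares those measurements against panels of
expert graders.

`retinotort` provides both, for image analysts and biostatisticians working
on retinal imaging:

* **Geometry** — the four reference centerline tortuosity metrics:
  the arc/chord ratio τ = L_c/L_x − 1 (Hart), the constant-sign
  curvature-segment density (n−1)/L_c · Σ(L_csi/L_xsi − 1) (Grisan), the
  curvature L^p aggregate (Σ|k_j|^p)^{1/p} (Trucco), and the chain-code
  inflection measure (n−1)/n · 1/L_c · Σ|K(p_i,k)| (Onkaew), plus the
  arc-length-weighted combination τ = Σ L_ci τ_ci / Σ L_ci that yields one
  score per retina.
* **Extraction** — fundus-style image → vessel tree: multiscale
  structure-tensor creaseness detection, thinning to a 1-px skeleton,
  junction-aware segment tracing, sub-pixel refinement and smoothing.
* **Agreement** — multi-rater ordinal rating analytics: clinical binary
  groupings, Cohen's kappa with interpretation bands, majority-vote
  consensus labels, consensus percentages.  The published marginal rating
  counts of a five-expert, 60-image grading study ship as fixtures.
* **Validation** — ROC/AUC of continuous tortuosity scores against binary
  consensus labels (with an exact Mann–Whitney cross-check), and single
  ROC points for categorical expert predictions.
* **Synthetic data** — annotated parametric vessels, rendered phantoms with
  ground-truth centerlines, and simulated rating panels with controllable
  rater reliability, so every stage can be validated without clinical data.

## Worked example

Render a single sinusoidal vessel phantom with known tortuosity and measure
it:

```python
import imageio.v3 as iio
from retinotort.synthetic import VesselSpec, render_phantom

spec = VesselSpec(family="sinusoid", length=200.0, amplitude=14.0,
                  half_waves=3, start=(28.0, 64.0), id="demo")
ph = render_phantom([spec], shape=(128, 256), width=5.0)
iio.imwrite("demo.png", (ph.raster * 255).astype("uint8"))
print(ph.vessels[0].hart)   # analytic arc/chord excess: 0.10124057540669917
```

```sh
$ retinotort measure demo.png --out report.csv
hart: 0.101536
grisan: 0.00270397
trucco: 3.51648
onkaew: 0.0125996
```

The measured Hart value 0.1015 recovers the analytic 0.1012 to 0.3%: the
vessel's path is 10.15% longer than its chord.  The non-zero Grisan and
Onkaew values reflect its two interior inflections (three half-waves), and
`report.csv` lists the same numbers per vessel plus a length-weighted TOTAL
row — with one vessel they coincide.

Other entry points follow the same pattern: `retinotort agree` runs the
kappa/consensus analysis on a ratings CSV, `retinotort roc` validates a
score column against binary labels, `retinotort simulate` generates
vessels, phantoms or rating panels, and `retinotort study --config
study.toml` runs the full measure → agreement → ROC pipeline into one
deterministic report bundle.  Everything is also available as a library
(`retinotort.geometry`, `.extraction`, `.agreement`, `.validation`,
`.synthetic`, `.workbench`).

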
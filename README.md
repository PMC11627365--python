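# parmap

Quantitative mapping of PAR protein dosage to polarity and
asymmetric-division phenotypes in *C. elegans* zygotes.

The one-cell *C. elegans* embryo divides asymmetrically: anterior PAR
proteins (PAR-3, PAR-6, PKC-3) and posterior PAR proteins (PAR-1, PAR-2)
form mutually exclusive cortical domains that position the mitotic
spindle and segregate fate determinants, producing a larger anterior
daughter (AB) and a smaller posterior daughter (P1) that divides ~2 min
later. `parmap` is a pipeline for asking how robust these outputs are to
protein dosage: it quantifies per-embryo protein dosage and cortical
concentration profiles from midplane fluorescence images, computes
polarity asymmetry indices and domain geometry, extracts division
phenotypes from spindle-pole tracks and two-cell masks, and maps
phenotype against dosage with LOWESS trends and moving-window variance
profiles. It is aimed at quantitative cell biologists running
RNAi-rundown or heterozygote experiments with single-embryo imaging.

## The core quantities

* **Cortical concentration** A(s): each cross-membrane linescan is fit
  to a Gaussian membrane ridge plus an error-function cytoplasmic step,
  `I(x) = A e^{-(x-c)²/2w_g²} + (C/2)(1 + erf((x-c)/w_e√2)) + O`;
  the Gaussian amplitude A is the membrane concentration at perimeter
  position s. Regional cortical levels are means of A(s) over the
  pole-centred 33% perimeter arcs.
* **Dosage**: whole-embryo mean fluorescence (autofluorescence-corrected,
  SAIBR-style spectral regression) normalized to the control cohort, so
  controls sit at 1.
* **Composite asymmetry index**
  `ASI = ((A_A − A_P) − (P_A − P_P)) / (A_A + A_P + P_A + P_P)`,
  the signal-weighted combination of aPAR (A) and pPAR (P) pole
  concentrations, each normalized to its wild-type peak: 1 for perfect
  complementary polarity, 0 for uniform.
* **Division phenotypes**: AB area fraction, AB→P1 furrow asynchrony,
  transverse spindle oscillation magnitude σ (population SD of off-axis
  pole displacement), final pole positions, and maximum outward pole
  velocity after spindle severing.
* **Dose-response**: LOWESS (local-linear, tricube) trends with
  bootstrap 95% bands, and Gaussian-moving-window (σ = 0.1 dosage units)
  phenotypic variance along the dosage axis.

A synthetic-embryo generator (`parmap.synthetic`) renders ground-truth
embryos — elliptical midplanes with logistic membrane domains,
autofluorescence bleed-through and read noise — plus rundown cohorts
with Hill dosage→phenotype maps (inflection at 50% dosage), bimodal
asymmetry regimes, spindle tracks and two-cell masks, so the entire
pipeline is testable without microscopy data. See `docs/methods.md` for
models, parameters and limitations.

## Worked example

Render a polarized embryo at 80% dosage with a target composite
asymmetry of 0.6, then measure it back:

```python
import numpy as np
from parmap import synthetic, cortex, polarity

spec = synthetic.polarized_embryo_spec(asi=0.6, dosage=0.8, seed=42)
image, truth = synthetic.render_embryo(spec)

contour = cortex.segment_embryo(image, channel=["apar", "ppar"], anterior_marker="apar")
st_all = cortex.straighten_cortex(image, contour, channel=["apar", "ppar"])
registration = cortex.fit_membrane_profiles(st_all)   # shared membrane midline
profiles = {}
for role in ("apar", "ppar"):
    st = cortex.straighten_cortex(image, contour, channel=role)
    profiles[role] = cortex.fit_membrane_profiles(st, fixed_center=registration)

m = polarity.pole_concentrations(
    profiles["apar"], profiles["ppar"],
    apar_peak=float(np.nanmax(profiles["apar"].amplitude)),
    ppar_peak=float(np.nanmax(profiles["ppar"].amplitude)),
)
print(f"perimeter: {contour.perimeter_um:.1f} um")
print(f"aPAR cortical means  anterior {cortex.cortical_mean(profiles['apar'], 'anterior'):.1f}"
      f"  posterior {cortex.cortical_mean(profiles['apar'], 'posterior'):.1f}")
print(f"composite ASI: {polarity.asi_composite(m):.3f}"
      f" (ground truth {truth.scalars['asi_true']:.3f})")
print(f"aPAR domain boundary: s_b = {polarity.domain_boundary(profiles['apar'], 'anterior').s_b:.3f}")
```

prints

```
perimeter: 127.6 um
aPAR cortical means  anterior 80.0  posterior 20.1
composite ASI: 0.599 (ground truth 0.600)
aPAR domain boundary: s_b = 0.249 from the anterior pole
```

The anterior aPAR plateau reads 80 (peak 100 × dosage 0.8), the
posterior plateau 20 (the (1−ASI)/(1+ASI) = 0.25 contrast), the measured
composite ASI recovers the generator's ground truth to 0.001, and the
domain boundary sits at the generator's 0.25 perimeter fraction.

A command-line interface mirrors the library:

```sh
parmap simulate cohort --out sim --seed 3
parmap trend --cohort sim/cohort.csv --pheno phenotype_asynchrony_s --dose dosage_true --out trend.csv
parmap varprofile --cohort sim/cohort.csv --pheno phenotype_asynchrony_s --dose dosage_true --out var.csv
parmap run --config pipeline.yaml          # end-to-end on a directory of TIFFs
```

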
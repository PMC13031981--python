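# microzoo

A reusable pipeline for quantifying microzooplankton (ciliate and
dinoflagellate) carbon biomass from settling-chamber micrographs and for
analysing how that community relates to grazing pressure and environmental
structure on a seasonal shelf transect. It is aimed at plankton ecologists
who count Lugol's-fixed samples on inverted microscopes, run dilution grazing
experiments, and want the downstream community statistics to be scripted,
seeded, and testable.

The package covers four stages, each usable on its own:

1. **Micrograph quantification** (`microzoo.micrograph`) — segment dark cells
   from a calibrated grayscale image, measure major/minor axes from the
   moment-equivalent ellipse (axis length = 4·√eigenvalue of the mask's
   pixel covariance), correct ciliate lengths for cilia picked up by the
   threshold, convert to biovolume assuming prolate spheroids
   (V = π/6·a·b²), carbon via the allometry pg C = 0.216·V^0.939, and
   aggregate to μg C L⁻¹ by group and 20 μm size class.
2. **Dilution grazing rates** (`microzoo.dilution`) — the two-point dilution
   method: apparent growth k = ln(Chl₂₄/Chl₀)/t in whole seawater (WSW) and a
   ~20% dilution; grazing g = (k_dil − k_WSW)/(1 − x); g is *zero* when the
   treatments do not differ significantly and *undetermined* when WSW growth
   significantly exceeds diluted growth; nutrient-amended vs unamended WSW
   separates μ_n from in situ μ.
3. **Environmental derivations** (`microzoo.environment`) — mixed layer depth
   as the shallowest depth with |T − T_surface| > 0.5 °C, diffuse attenuation
   K_d from ln(PAR)–depth regression (or a beam-attenuation calibration for
   night casts), mean mixed-layer light I_m = I₀(1 − e^(−K_d·MLD))/(K_d·MLD),
   and chlorophyll size fractions from GF/F vs >10 μm filters.
4. **Community statistics** (`microzoo.community`) — relative biomass,
   Bray-Curtis dissimilarity with ANOSIM (999 permutations), type-III two-way
   season × region ANOVA, a Pearson screen (r > 0.70, p < 0.05) that prunes
   co-correlated explanatory variables, z-scored redundancy analysis (RDA)
   with a global permutation test, an RDA-space centroid rule that flags
   compositional outliers (closer to the opposite season's centroid than
   half the distance to their own, or >2.5 SD beyond their own season's mean
   centroid distance), seasonal/regional summaries, and season-stratified
   grazing–biomass Pearson correlations.

A synthetic-data module (`microzoo.synthetic`) generates every input with
known ground truth — rendered micrographs with anti-aliased ellipsoidal
cells and optional cilia fringes, seasonal community tables, dilution
experiments, CTD profiles, and grazing-rate columns that depend on biomass
in winter only — so the whole pipeline is verifiable end to end without any
field data.

## Worked example

Generate a six-year synthetic study and analyse it from the shell:

```bash
microzoo simulate --seed 3 --outdir sim
microzoo stats --biomass sim/biomass.csv --env sim/environment.csv \
    --n-perm 999 --seed 1 --outdir stats
```

which prints

```json
{
  "anosim": {"grouping": "season", "R": 0.547, "p": 0.001},
  "rda": {
    "retained": ["pct_chl_small", "mld_m", "salinity"],
    "constrained_fraction": 0.369,
    "p": 0.001,
    "n_outliers": 4
  }
}
```

ANOSIM's R = 0.55 (p = 0.001) says seasonal groups are well separated in
Bray-Curtis space; the Pearson screen dropped nitrate+nitrite as
co-correlated, and the three retained variables constrain 37% of the
compositional variance (significant at the permutation floor of 1/1000).
Rates from the bundled dilution experiments:

```bash
microzoo rates --input sim/dilution.csv --out rates.csv
```

```text
experiment_id       mu     mu_n        g   status  p_value
         exp0 0.193212 0.200098 0.000000     zero 0.055315
         exp1 0.426309 0.469348 0.204218 measured 0.039418
         exp2 0.509947 0.514290 0.279476 measured 0.006976
```

`exp0` illustrates the classification rule: with only duplicate bottles the
treatment difference missed the 5% level (p = 0.055), so its grazing rate is
reported as zero rather than as an unreliable number. And the light climate
from the synthetic CTD cast:

```bash
microzoo env --ctd sim/ctd.csv --surface-par 30 --out env.json
# {"mld_m": 25.24, "kd_per_m": 0.1, "im": 10.93, ...}
```

The 0.5 °C rule finds the mixed layer at the first sampled depth below the
built-in 25 m step, K_d is recovered exactly from the noiseless PAR profile,
and the mean mixed-layer light is about a third of surface PAR.

The same operations are available as library calls; see the module
docstrings and `docs/methods.md` for the underlying models, parameter
defaults, and numerical choices.

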
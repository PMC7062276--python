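# mcpsize

Apparent-size analysis of bacterial microcompartments (MCPs) across imaging
and light-scattering techniques.

Protein-shelled organelles such as the Pdu microcompartment of *Salmonella*
are ~100–140 nm polyhedral shells, and the diameter a study reports for them
depends strongly on how they were measured: negative-stain TEM collapses
them, HMDS solvent exchange and critical-point-dried SEM partially preserve
them, cryo-TEM keeps them hydrated and fully inflated, and ultra-thin-section
(UTS) TEM cuts each particle at a random height so every recorded diameter is
a chord, not the true width. Ensemble methods (DLS, NTA) add their own
conventions on top. `mcpsize` packages the quantitative machinery needed to
compare these numbers on a common footing:

- **Thin-section stereology** (`mcpsize.geometry`). For a sphere of diameter
  *D* cut at distance *r* from its centre, the section diameter is
  *d(r) = D·√(1 − (2r/D)²)*. Averaging over the sphere with the volume
  element (*r² dr* weighting) gives **E[d] = (3π/16)·D ≈ 0.589·D** — a ~41 %
  underestimation — while classical uniform-offset plane sampling gives
  (π/4)·D. Both schemes are implemented analytically and as Monte-Carlo
  simulators, for spheres and for irregular convex polyhedra (sections are
  measured by their maximum Feret diameter, matching the manual
  longest-diameter protocol). A left-truncation model captures the detection
  limit of image analysis — the smallest sections go unrecognised — and
  `fit_detection_limit` inverts it: given an observed apparent/true mean
  ratio it returns the threshold that explains the gap between the predicted
  41 % and an observed ~28 % shortfall.
- **Calibrated synthetic data** (`mcpsize.synthetic`). Five technique
  datasets (N = 300 each, 3 replicates × 100) calibrated to
  102 ± 17, 124 ± 17, 126 ± 17, 138 ± 21 and 99 ± 32 nm (TEM, TEM+HMDS,
  SEM, cryo-TEM, UTS-TEM), UTS data generated by *actually sectioning* a
  simulated population, DLS correlograms
  `g₂(τ) = 1 + β·[Σᵢ wᵢ e^(−q²Dᵢτ)]²`, and per-particle NTA samples with a
  small aggregate subpopulation.
- **Cumulant analysis** (`mcpsize.dls`). `CumulantModel(correlogram).fit()`
  returns the Z-average (intensity-weighted harmonic-mean hydrodynamic
  diameter, via Stokes–Einstein at the instrument's q) and the
  polydispersity index μ₂/Γ̄², plus Rayleigh-regime intensity ↔ number ↔
  volume PSD reweighting (I ∝ N·d⁶, V ∝ N·d³).
- **Statistics** (`mcpsize.stats`). Box-whisker summaries with Tukey
  1.5·IQR outliers, percent shifts between technique means, one-way ANOVA,
  Welch/pooled two-tailed t-tests, and SD-ratio ranges.

## Worked example

```python
from mcpsize import geometry, synthetic, dls, stats

# stereology: what sectioning does to a 138 nm sphere
model = geometry.SectioningModel(138.0)
print(geometry.underestimation_percent(model))      # 41.09513774519138
limit = geometry.fit_detection_limit(99/138, model, size_sd=21.0)
print(limit)                                        # 61.733508520033186

# DLS: simulate and refit a near-monodisperse population
psd = dls.lognormal_psd(z_ave_nm=122.04, pdi=0.045)
fit = dls.cumulant_fit(synthetic.simulate_correlogram(psd))
print(fit.z_ave_nm, fit.pdi)                        # 122.0927831891339 0.04235929771713895
```

The first number says an infinitely thin random section of a perfect sphere
under volume-element weighting underreports the diameter by 41.1 % on
average; the fitted 61.7 nm detection limit is the smallest recognisable
section size that reconciles that prediction with an observed mean ratio of
99/138 for a Gaussian 138 ± 21 nm population. The cumulant fit recovers the
generating Z-average to 0.04 % and the PDI to within 0.003.

The full pipeline, from data generation to a juxtaposed report:

```bash
mcpsize reproduce --seed 1 --out reproduction
```

prints (abridged):

```
One-way ANOVA: F(4, 1495) = 179.59, p = 1.01e-125  (reference: p < 0.001)

Percent differences between technique means (reference in parentheses)
   TEM+HMDS vs TEM        +21.57%  (ref +22%)
        SEM vs TEM        +23.53%  (ref +24%)
   cryo-TEM vs TEM        +35.29%  (ref +35%)
   cryo-TEM vs SEM         +9.52%  (ref +10%)
    UTS-TEM vs cryo-TEM   -28.26%  (ref -28%)

UTS SD ratio range vs other techniques: 1.52-1.88  (ref 1.5-1.9)

Ultra-thin-section stereology
  analytic underestimation (volume-weighted): 41.1%  (ref ~41%)
  detection limit fitted to observed ratio 0.717: 61.7 nm
  sectioned population mean (10000 particles): 99.1 nm  (ref 99 nm)

DLS cumulant recovery
  Z-average: 122.09 nm  (ref 122.04 nm)
  PDI:       0.0424  (ref 0.045)
```

Other subcommands: `generate-data`, `simulate-sections`, `analyze-sizes`,
`simulate-dls`, `fit-cumulants`, `reweight-psd`, `report` (box-whisker
plot). All accept `--seed`; every CSV output is byte-identical across reruns
with the same seed.

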
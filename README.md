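# nemech

Quantitative analysis of nuclear-envelope (NE) mechanics and organisation
in the *C. elegans* germ line, built around two kinds of raw data:

1. **Mechano-node-pore sensing (mechano-NPS) current traces.**  A nucleus
   driven through a segmented microfluidic channel produces a current
   pulse: a shallow sub-pulse in the wide *sizing* segment, a brief
   recovery at the *node*, and a deeper sub-pulse in the narrow
   *contraction* segment.  From the sizing drop ΔI_S the nuclear diameter
   d_n follows from the resistive-pulse relation

   ΔI/I = d³ / (D_e² L) · 1/(1 − 0.8 (d/D_e)³),   D_e = √(4wh/π),

   the applied strain is ε = (d_n − w_c)/d_n for a contraction channel of
   width w_c, and the whole-cell deformability index

   wCDI = L_c · h · t_s / (d_n² · t_c)

   is a dimensionless, size-normalised inverse contraction transit time:
   stiff nuclei cross the contraction slowly (large t_c, small wCDI), so
   wCDI is inversely related to the Young's modulus.  Nuclei no wider
   than the contraction channel (d_n ≤ w_c, i.e. ε = 0) are excluded from
   wCDI statistics.

2. **Fluorescence imaging of the NE.**  Angular intensity profiles around
   the nuclear periphery give the LINC-complex *clustering index* (sample
   SD / mean, a coefficient of variation), stage-normalised mean
   intensities, and *polarization profiles* in which the brightest point
   is rotated to 180° and the intensity at 0° is normalised to 1 (the
   170°–190° mean quantifies a polar cap).  Further tools cover patch
   tracking with drift correction and mean speeds, 3D nuclear volume
   segmentation, alignment of NE/synaptonemal-complex (SC) collapse time
   series on their contact point with piecewise shrinkage-rate fits, and
   zone-based scoring of collapse/pairing/synapsis fractions along the
   distal–proximal gonad axis, with the matching statistics (Welch ANOVA,
   Games–Howell, Benjamini–Hochberg, proportion tests, power analysis).

Every stage is driven by a seed-reproducible synthetic-data generator
with known ground truth (`nemech.synthetic`), so the full pipeline is
testable without any external data.

## Worked example

Simulate two nucleus populations that differ only in deformability
("control" vs "depleted", softness 0 vs 2), run the full trace analysis,
and compare wCDI between groups:

```bash
nemech demo --seed 7 --out demo_run
```

prints

```json
{
  "groups": {
    "control":  {"n_included": 49, "mean_wcdi": 505.6, "mean_strain": 0.130},
    "depleted": {"n_included": 47, "mean_wcdi": 559.9, "mean_strain": 0.143}
  },
  "welch_anova": {"F": 6.10, "df1": 1, "df2": 93.99, "p": 0.0153}
}
```

Out of 50 simulated nuclei per group, 49 and 47 are wider than the
2.9-µm contraction channel and enter the wCDI comparison; the softer
("depleted") population clears the contraction faster and shows the
higher mean wCDI, and Welch's heteroscedastic ANOVA puts the difference
at p ≈ 0.015.  The per-event tables (`events_*.csv`), Games–Howell
pairwise table and a provenance record (config hash, seed, versions)
are written to `demo_run/`.

Other subcommands (`nemech --help`): `simulate-nps`, `analyze-nps`,
`simulate-rings`, `quantify-rings`, `polarize`, `track`, `collapse`,
`zones`, `stats`.

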
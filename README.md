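# cfm-diatom

A steady-state, coarse-grained carbon-flux model of phytoplankton
growth, built to ask one question quantitatively: **why do diatoms grow
faster than other phytoplankton of the same size, and why does growth
decline with cell volume?**

The answer the model encodes has three parts:

1. **Diatoms are carbon-cheap.** Cellular carbon quotas follow
   empirical allometries, Q_C = A_C·V^B_C, and the diatom curve sits
   well below that of other photosynthetic protists, so a diatom needs
   less fixed carbon to build a daughter cell of the same volume.
2. **The silica frustule is nearly free.** Depositing silica costs
   only 0.167 mol C per mol Si; combined with a cellular Si:C ratio of
   0.163 this is E_Si ≈ 0.027 mol C per mol biomass C — about **1.6%**
   of the total carbon cost of growth, versus the 1.691 mol C it takes
   to produce one mole of biomass carbon (biosynthesis plus growth
   respiration).
3. **Big cells shade themselves.** Light attenuates along chords
   through the cell (Beer's law), so the per-volume photosynthesis rate
   falls with size (the package effect), and growth rate declines with
   volume once cells are much larger than the attenuation length.

## The model

At steady state the carbon budget per cell,

    dQ_C/dt = F_Pho − μ·Q_C·(1 + E_μ + E_Si) = 0,

yields the nutrient-replete growth rate

    μ = F_Pho / [Q_C·(1 + E_μ + E_Si)],

with Q_C = A_C·V^B_C, E_μ the growth respiration factor, and
E_Si = (C cost per Si)·(Si:C) the silica-deposition cost (zero for
non-diatoms). An optional excretion term E_ex adds to the denominator.
The photosynthetic source is the volume integral of a saturating
photosynthesis–irradiance response,

    F_Pho = ∫_cell p_max·(1 − e^(−I(x)/I_sat)) dV,
    I(x) = I_0·e^(−k_att·s(x)),

over a spherical cell under a collimated beam, with s the path length
from the illuminated surface. A counterfactual taxon class
(`diatom_no_si`) prices the frustule like ordinary biomass,
E_Si = (1 + E_μ)·Si:C, isolating what the cheap frustule is worth.

The companion `transcript_budget` module implements the ocean-survey
transcript comparison that tests the structural-replacement hypothesis:
per-taxon relative transcript abundances (reads for a function divided
by all reads of that taxon in a sample) compared pairwise between
diatoms and other photosynthetic protists for ribosomal-protein and
cytoskeleton (actin, tubulin) transcripts, plus a seeded synthetic
metatranscriptome generator so the pipeline runs without downloads.

## Worked example

```python
import numpy as np
from cfm_diatom import silica_fraction_of_cost
from cfm_diatom.config import default_config, cell_parameters
from cfm_diatom import experiments as ex

cfg = default_config()
print("silica share: %.4f%%" % (100 * silica_fraction_of_cost(cell_parameters(cfg, "diatom"))))
v = np.array([10.0, 100.0, 1e4, 1e6])
print(ex.sweep_growth(["diatom", "other", "diatom_no_si"], v, cfg).to_string(index=False))
```

prints

```
silica share: 1.5843%
       group  volume_um3   qc_molC  fpho_molC_per_day  mu_per_day  silica_fraction
      diatom          10 7.386e-14          2.314e-13       1.824          0.01584
      diatom         100 5.616e-13           1.93e-12           2          0.01584
      diatom       1e+04 3.247e-11          6.853e-11       1.229          0.01584
      diatom       1e+06 1.877e-09          1.533e-09      0.4753          0.01584
       other          10 1.565e-13          2.314e-13      0.8747                0
       other         100  1.36e-12           1.93e-12      0.8394                0
       other       1e+04 1.027e-10          6.853e-11      0.3948                0
       other       1e+06 7.752e-09          1.533e-09      0.1169                0
diatom_no_si          10 7.386e-14          2.314e-13       1.593           0.1402
diatom_no_si         100 5.616e-13           1.93e-12       1.747           0.1402
diatom_no_si       1e+04 3.247e-11          6.853e-11       1.073           0.1402
diatom_no_si       1e+06 1.877e-09          1.533e-09      0.4152           0.1402
```

Reading the table: all three groups receive the identical per-cell
photosynthesis rate F_Pho (`fpho_molC_per_day`), so the growth-rate
differences are pure carbon economics. The diatom curve peaks at
2 d⁻¹ near 100 μm³ and declines with volume (self-shading); diatoms
out-grow other protists at every volume because their quota
(`qc_molC`) is smaller; and pricing the frustule like biomass
(`diatom_no_si`) multiplies the whole diatom curve by the constant
1.718221/1.966633 ≈ 0.8737 while raising the silica share of the
carbon cost from 1.6% to 14%.

The transcript side, on synthetic survey data (66 samples, seed 1):

```python
from cfm_diatom import transcript_budget as tb
ra = tb.normalize(tb.synthesize_metatranscriptome(n_samples=66, seed=1))
r = tb.paired_comparison(ra, "ribosomal_protein", "diatom", "other_photosynthetic_protist")
print(r.n_pairs, r.fraction_above, round(r.median_log2_ratio, 3))  # 66 1.0 0.584
```

— diatom ribosomal-protein shares sit above the 1:1 line in all 66
samples (median log2 ratio 0.584 ≈ the generated +50% effect), while
the same comparison for actin gives a median log2 ratio of −1.01,
recovering the generated cytoskeleton reduction.

A CLI mirrors the library: `cfm-diatom sweep|fate|compare|calibrate`
and `cfm-diatom transcripts simulate|normalize|compare`; every output
table carries a header (version, config hash, seed) sufficient to
reproduce it.

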
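# pdukinetics

Systems-level kinetic modelling of the encapsulated 1,2-propanediol
utilization (Pdu) pathway in *Salmonella enterica*, for researchers
studying how bacterial microcompartment geometry shapes pathway flux.

Pdu enzymes are packaged inside protein shells: polyhedral
microcompartments (MCPs, modelled as 140 nm spheres, 15 per cell) in the
wild type, or elongated microtubes (MTs, modelled as 50 nm cylinders
spanning the 2.5 µm cell) when the vertex protein PduN is absent.  The
shell is a diffusion barrier that retains the toxic intermediate
propionaldehyde near the enzymes that consume it.  Because a sphere and
a cylinder cannot share both surface area and volume, the two geometries
trade off transport area against enzyme concentration — for the modelled
dimensions the surface-to-volume fold is 2·r_s/(3·r_c) ≈ 1.9.

## Model

Five metabolites (1,2-propanediol, propionaldehyde, propionyl-CoA,
1-propanol, propionate; concentrations in mM) are tracked in three
well-mixed regions — compartment lumen, cytosol, external medium.  Per
cell, with N compartments of shell area A_c and volume V_c:

    lumen:    dc/dt = (k_c·N·A_c/(N·V_c))·(c_cyt − c_lum) + R_CDE, R_P, R_Q
    cytosol:  dc/dt = (k_c·N·A_c/V_cyt)·(c_lum − c_cyt)
                    + (k_m·A_cell/V_cyt)·(c_ext − c_cyt) + R_LW
    external: dc/dt = −ρ(t)·k_m·A_cell·(c_ext − c_cyt)

All enzymes follow Michaelis–Menten kinetics: PduCDE (diol dehydratase,
irreversible) and the reversible PduP/PduQ (aldehyde/alcohol
dehydrogenase) act in the lumen; the lumped PduL/PduW step
(propionyl-CoA → propionate, irreversible) acts in the cytosol.  A
single shell permeability k_c applies to every species (cylinder end
caps get a separate multiplier, 0 = closed), and the shared medium is
depleted in proportion to the time-varying cell density ρ(t).

The package provides geometry matching (equal-volume / equal-area MT
limits), a stiff-capable simulator with summary statistics (onset,
depletion, peak, windowed doubling times), calibration of
{k_c, vmax_P, vmax_Q} against the observed timescale and toxicity
criteria, normalized local sensitivity analysis, and a synthetic-data
generator emulating the growth and HPLC measurements (biphasic growth
with doubling times 3.17 h → 9.2 h, 3 replicates sampled every 3 h,
5% lognormal noise, 0.5 mM detection floor).

## Worked example

```python
from pdukinetics import (default_parameters, GrowthModel,
                         generate_growth_curve, compare_geometries)

params = default_parameters()          # calibrated base case: 15 x 140 nm MCPs
growth = generate_growth_curve(GrowthModel())
results, summary = compare_geometries(params, growth)
cols = ["scenario", "compartment_count", "total_area_um2",
        "pdo_depletion_h", "prop_onset_h", "peak_external_pald_mM"]
print(summary[cols].round(3).to_string(index=False))
```

prints

```
    scenario  compartment_count  total_area_um2  pdo_depletion_h  prop_onset_h  peak_external_pald_mM
        base             15.000           0.924           19.742         9.101                 15.816
equal_volume              4.390           1.724           19.703         9.193                 15.864
  equal_area              2.352           0.924           19.742         9.100                 15.816
```

Reading the table: starting from 55 mM external 1,2-propanediol, the
base MCP model depletes the substrate at 19.7 h (inside the observed
10–20 h window), external propionate appears shortly after 9 h, and
propionaldehyde peaks below the 16 mM toxicity threshold.  Matching MTs
by total volume gives 1.87× the shell area (0.924 → 1.724 µm²) and a
strictly higher propionaldehyde peak, while matching by area leaves the
external profiles essentially unchanged — compartment surface area, not
shape, is what the external dynamics see.

A CLI mirrors the library: `pdukin simulate|compare-geometries|
calibrate|fit|sensitivity|synth --config run.yaml` (see
`pdukin --help`).

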
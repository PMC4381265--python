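# smnrisk

Whole-body dose reconstruction and lifetime second-cancer risk projection
for craniospinal irradiation (CSI), comparing passively scattered proton
therapy with conventional photon therapy.

Children cured of medulloblastoma by CSI face a substantial lifetime risk of
a subsequent malignant neoplasm (SMN) induced by the treatment itself — both
by the therapeutic field and by stray radiation (photon leakage and scatter,
or proton-induced secondary neutrons). Quantifying that risk per organ, and
how much of it proton therapy avoids, requires reconstructing the equivalent
dose everywhere in the body, not just in the target. `smnrisk` implements
that reconstruction as a reusable, tested pipeline for medical physicists
and risk modellers:

* **Voxel dosimetry** — equivalent dose $H_v = \bar{w}_R \cdot D_v$
  ($\bar{w}_R$ = 1 for photons, 1.1 for therapeutic protons, 9.2 / 9.0 for
  external / internal secondary neutrons), mass-weighted mean organ dose
  $H_T = \sum_{v\in T} H_v \rho_v \big/ \sum_{v\in T} \rho_v$,
  CT-to-density calibration, DVHs, remainder-volume derivation, and an
  image-truncation correction (ratio of imaged to total body mass, 0.726
  for the bundled case) for volumes cut off by the CT extent.
* **Stray-neutron handling** — external + internal neutron combination and
  normalization of per-source-particle Monte Carlo output to the
  prescription through a beam normalization volume (BNV):
  $H_T = (H_T/\mathrm{sp}) \cdot H^{\mathrm{TPS}}_{\mathrm{BNV}} /
  (H_{\mathrm{BNV}}/\mathrm{sp})$.
* **Out-of-field photon dose** — three approaches: planning-system values
  as-is; volume-weighted averaging with TLD-style point measurements gated
  by a ±60 % / 5 % sensitivity rule; and analytic replacement of voxels more
  than 1 cm outside the 50 % isodose surface with a fitted two-Gaussian
  function of distance from the field edge,
  $H(r) = \bar{w}_R D_{Rx} \tfrac{1}{100}\sum_{i=1,2}
  \frac{\alpha_i}{\sqrt{2\pi}\sigma_i} e^{-(r-\mu_i)^2/2\sigma_i^2}$.
* **Risk engine** — linear-no-threshold projection
  $I_T = (I_T/H_T)\cdot H_T$, $M_T = (M_T/H_T)\cdot H_T$ with
  BEIR-VII-style coefficients (age interpolation, DDREF removal except
  leukemia, ICRP-60 NMSC coefficients, 0.1 thyroid lethality), aggregate
  proton:photon ratios and dose-component risk attribution.
* **Synthetic phantom generator** — a parametric torso+head voxel phantom
  with the 13 contoured volumes, CSI field geometry, modality-specific dose
  component grids and TLD samples, so the entire pipeline is testable with
  no external data.

The package bundles the organ-dose and risk-coefficient tables of a worked
reference case — a 13-year-old girl prescribed 23.4 Gy-RBE CSI, planned with
protons at one institution and photons at another — so the risk engine can
be exercised end to end without any dose grids.

## Worked example

```bash
smnrisk reproduce
```

applies the bundled risk coefficients (%/Sv) to the bundled proton and
photon organ equivalent doses (Sv) and prints, among others:

```
                     proton_to_photon
incidence_incl_nmsc              0.46
incidence_excl_nmsc              0.30
mortality                        0.39

sites with incidence ratio >= 1 (2-dec rounding): ['nmsc']
attribution [proton_I]: primary=0.777, external neutron=0.157, internal neutron=0.066
```

Read: proton CSI carries 46 % of the photon-CSI summed SMN incidence risk
(30 % once non-melanoma skin cancer is excluded) and 39 % of the summed
mortality risk; skin is the only site where the two modalities are
essentially equivalent; and about a quarter (0.157 + 0.066) of the proton
incidence risk comes from stray neutrons rather than the therapeutic beam.

A fully synthetic run (no bundled tables — phantom, dose grids, organ means,
risks all computed):

```bash
smnrisk synth --modality proton --seed 1 --out proton.h5
smnrisk synth --modality photon --seed 2 --out photon.h5
smnrisk run proton.h5 --outdir out
smnrisk run photon.h5 --approach model --outdir out
smnrisk compare out/organ_doses_proton.csv out/organ_doses_photon.csv
```

Or from Python:

```python
from smnrisk import PhantomConfig, generate_case, photon_organ_doses

case = generate_case(PhantomConfig(modality="photon", noise_sigma=0.0, seed=1))
doses = photon_organ_doses(case, approach="model")   # organ -> H_T in Sv
```

## Layout

| module | contents |
| --- | --- |
| `smnrisk.grids` | dose/density grids, structure sets, organ means, DVH, truncation |
| `smnrisk.neutron` | neutron component sums, BNV prescription normalization |
| `smnrisk.out_of_field` | isodose surfaces, two-Gaussian model, sensitivity rule, volume weighting |
| `smnrisk.risk` | coefficient preparation, LNT projection, ratios, attribution |
| `smnrisk.phantom` | synthetic phantom and dose generator |
| `smnrisk.pipeline` | per-modality orchestration, modality comparison |
| `smnrisk.io` | HDF5 case container, CSV tables |
| `smnrisk.cli` | `smnrisk synth / run / reproduce / compare` |

See `docs/methods.md` for the scientific assumptions, defaults and
limitations.
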
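# cherenkov-polarimetry

Polarization imaging of Cherenkov emission for water-tank radiotherapy
dosimetry.

Megavoltage photon and electron beams generate Cherenkov light in water,
and a camera beside the tank can image it — but the emission is
anisotropic (it is produced on a cone at cos θ_c = 1/(βn) around each
electron's path), so the raw signal is not proportional to dose.
Cherenkov light is, however, linearly polarized.  This package implements
the analysis chain that exploits that: measure the scene through a
rotating polarizer at four angles, decompose each pixel with Malus' law

    I(α₀) = I_pol cos²(α₀ − α) + I_unpol,

into a polarized amplitude I_pol, an unpolarized offset I_unpol, the
degree of linear polarization DoLP = I_pol/(I_pol+I_unpol)×100 and the
angle of linear polarization α, then correct the polarized component for
the emission anisotropy using Monte Carlo–derived polar/azimuthal angular
distributions and the camera geometry,

    D(x, y) ∝ C_θ(x, y) · C_φ(x, y) · I_pol(x, y),

and extract projected percent-depth-dose curves, lateral profiles and
field sizes from the corrected image.  It is aimed at medical-physics
researchers prototyping camera-based water-tank dosimetry.

The package contains:

- `physics` — closed-form Cherenkov physics: emission angle, threshold
  energy (264 keV in water, 149 keV in polyvinyl toluene), Frank–Tamm
  photon yield, photon polarization geometry;
- `polarimetry` — the four-angle closed-form Malus solver (Stokes
  Q/U quadrature) and a bounded least-squares fit for general angle sets;
- `image_prep` — temporal median filtering, background subtraction, cos⁴
  vignetting fit and flat-field correction;
- `mc` — a simplified condensed-history electron transport (tabulated
  stopping power, Highland multiple scattering) plus single-Compton
  photon transport, tallying Cherenkov photon directions into per-voxel
  polar/azimuthal distributions;
- `correction` — pixel→viewing-angle mapping and the C_θ/C_φ correction
  maps;
- `metrics` — PPDD, profiles, FWHM field size, difference statistics;
- `synthetic` — a forward simulator rendering four-angle stacks (with
  background, flat frame, vignetting, Poisson/read noise and transient
  spikes) from a known ground truth, so the whole chain is testable
  without any measurement data;
- `cli` — `cherenkov-polarimetry` with subcommands `synth`, `prep`,
  `solve`, `mc`, `correct`, `metrics` and `run`.

## Worked example

The repository ships a demo configuration that renders a synthetic
6 MeV electron-beam measurement (DoLP 42% in the beam core, 6×6 cm²
field), runs the full chain and reports recovery statistics:

```sh
cherenkov-polarimetry run --config examples/demo_6mev.yaml --out scratch/demo
```

prints (seconds of runtime):

```json
{
  "beam": "6MeV",
  "seed": 1,
  "dolp_roi_mean_percent": 41.98397808051051,
  "dolp_roi_std_percent": 0.32762222161556315,
  "d_max_cm": 1.4849999999999994,
  "field_size_cm": 5.9991607380251235,
  "ppdd_diff_mean_pp": 0.0556897184425414,
  "ppdd_diff_std_pp": 0.08723837071889848,
  "profile_diff_mean_pp": -0.07139069059391522,
  "profile_diff_std_pp": 0.3413274059138378
}
```

Reading: the solver recovers the generating DoLP (42%) to within shot
noise from a 1×1 cm² region at d_max; the anisotropy-corrected dose image
reproduces the ground-truth PPDD and d_max profile to well under 1
percentage point on average; the FWHM field size matches the 6 cm field.
Running the same command twice yields bit-identical artifacts (the
manifest in the output directory records seeds and content hashes).
Without the correction, the polarized electron-beam image underestimates
the shallow-depth dose by tens of percentage points — the anisotropy is
the dominant systematic the method removes.

Library use mirrors the CLI:

```python
from cherenkov_polarimetry import (Scenario, generate_ground_truth,
                                   render_stack, solve_four_angles,
                                   build_correction_maps, apply_correction,
                                   extract_ppdd)

sc = Scenario(beam="18MV", seed=2)
rendered = render_stack(generate_ground_truth(sc), sc)
maps = solve_four_angles(rendered.stack())
cmaps = build_correction_maps(rendered.distributions, rendered.geometry, "photon")
ppdd = extract_ppdd(apply_correction(maps.i_pol, cmaps, rendered.geometry))
print(ppdd.d_max)   # 3.045 — the 18 MV preset puts d_max at 3.05 cm
```

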
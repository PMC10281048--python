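# oaphantom

Stochastic three-dimensional numerical breast phantoms (NBPs) and lesion
phantoms (NLPs) for virtual imaging trials of optoacoustic (photoacoustic)
computed tomography.

Quantitative optoacoustic breast imaging systems cannot be compared through
human trials at the design stage, so candidate designs are evaluated
virtually against ensembles of digital phantoms that carry clinically
relevant variability in anatomy and tissue properties. `oaphantom`
generates such ensembles: labeled anatomical volumes with realistic
superficial and interior blood vasculature, malignant lesion models with a
necrotic core and a peripheral-angiogenesis (PA) shell, and voxel-wise
functional, multi-wavelength optical, and acoustic property maps. The
exported maps are drop-in inputs for Monte-Carlo photon transport and
time-domain acoustic wave solvers.

## The models

**Anatomy.** Breast size/shape parameters per BI-RADS density type (A,
almost entirely fatty, through D, extremely dense) are drawn from truncated
Gaussian distributions TN(μ, σ, l, u) consistent with a prone scan inside
an 85 mm hemispherical aperture. A built-in parametric fixture generator
produces labeled half-ellipsoidal volumes (skin shell, nipple, fat /
glandular partition, ligament septa, TDLU/duct lesion-candidate sites);
externally produced uint8 label volumes can be ingested instead (raw +
sidecar, or NIfTI). Interior arterial/venous trees grow from anatomically
placed chest-wall entry points (internal mammary, thoraco-acromial, lateral
thoracic, subscapular/thoraco-dorsal, intercostal); superficial vasculature
— the dominant feature of clinical optoacoustic images — is synthesized at
a fixed 0.375 mm depth under the skin by band-pass filtering a random
field, skeletonizing, draping the curves over the sub-skin shell, and
re-inflating them to ~0.75 mm tubes.

**Lesions.** A spiculated viable-tumor-cell (VTC) mask is eroded by a
0.75 mm spherical structuring element to carve the necrotic core and
dilated by a 5 mm element to define the PA shell.

**Functional maps.** Per phantom, each tissue draws oxygen saturation *s*
and volume fractions of blood (f_b), water (f_w), fat (f_f), and
melanosome (f_m), with total hemoglobin concentration of blood
c_tHb ~ U(1860, 2325) μM. Spatial variation of *s* (oxygen diffusion) and
of f_b (peri-tumoral angiogenesis) comes from the steady diffusion–
reaction equation

    −μ Δu(r) + Σᵢ χᵢ(r) (u(r) − ūᵢ) = 0

with zero-flux boundaries, where χᵢ indicates the tissues that impose
their sampled targets ūᵢ.

**Optical maps.** Absorption mixes the pure-chromophore spectra:
μ_a(r, λ) = Σᵢ fᵢ(r) μ_{a,i}(λ), with oxy/deoxy blood fractions f_b·s and
f_b·(1−s) and μ_{a,oxy/deoxy} = ln(10)·c_tHb·ε_{HbO₂/Hb}(λ). Scattering
follows μ_s(r, λ) = μ_s′(r, λ_ref)/(1−g) · (λ/λ_ref)^(−b) with
λ_ref = 500 nm, the pair (μ_s′, b) jointly sampled per tissue from one
shared uniform variate to preserve their observed correlation.

**Acoustic maps.** Sound speed, density, and attenuation α₀ are drawn per
tissue per phantom; the attenuation power-law exponent y is a homogeneous
per-phantom scalar set by breast type (1.1151 / 1.1642 / 1.2563 / 1.3635
for A–D), matching what time-domain wave solvers support.

**Validation.** The breast-volume percentage occupied by blood vessels
(clinical optoacoustic estimates average ≈ 0.44 %) and the spatially
averaged effective attenuation μ_eff = ⟨√(3 μ_a (μ_a + μ_s′))⟩ tie
generated ensembles back to clinical observations.

## Worked example

```python
import oaphantom as oa

cfg = {
    "breast_type": "B",
    "voxel_size_mm": 0.5,          # desk-scale; default is 0.125 mm
    "seed": 42,
    "shape": {"a1t": 30, "a1b": 30, "a2l": 30, "a2r": 30, "a3": 28},
    "lesions": {"count": 1, "diameters_mm": [6.0], "irregularity": 0.5,
                "with_core_and_pa": True},
}
bundle = oa.generate_phantom(cfg)
vol = bundle.volume
breast = vol.breast_mask()
print("dims:", vol.dims, " voxel:", vol.voxel_size, "mm")
print("vessel volume: %.3f %%" % oa.vessel_volume_percentage(vol))
print("ctHb,blood: %.1f uM" % bundle.functional.ctHb_blood)
print("mueff(800 nm): %.3f 1/mm" % oa.estimate_mueff(bundle.optical, vol, 800.0))
print("acoustic y:", bundle.acoustic.y)
```

prints

```
dims: (58, 124, 124)  voxel: 0.5 mm
vessel volume: 0.566 %
ctHb,blood: 2060.2 uM
mueff(800 nm): 0.244 1/mm
acoustic y: 1.1642
```

The vessel percentage counts artery+vein voxels against all breast voxels
(small fixtures run high because the sub-skin shell is a larger share of
the volume); c_tHb is this phantom's blood hemoglobin draw; μ_eff is the
diffusion-theory effective attenuation averaged over breast tissue at
800 nm (the oxy/deoxy isosbestic wavelength); y is the type-B attenuation
exponent. The same config with the same seed regenerates the bundle
bit-identically.

A command-line interface covers the common flows:

```bash
oaphantom generate --breast-type C --seed 1 --voxel-size-mm 0.125 \
    --wavelengths 757,800,850 --lesions 4 --out phantom_out/
oaphantom validate-config my_config.yaml
oaphantom metrics --labels phantom_out/labels.raw
```

## Layout

- `oaphantom.anatomy` — label-volume model, shape sampling, fixture
  anatomy, vessel-tree growth
- `oaphantom.subskin` — sub-skin vasculature synthesis
- `oaphantom.lesion` — VTC masks, necrosis/PA morphology, insertion
- `oaphantom.functional` — property draws and diffusion–reaction solves
- `oaphantom.optical` / `oaphantom.spectra` — absorption & scattering maps
- `oaphantom.acoustic` — sound speed / density / attenuation maps
- `oaphantom.validation` — vessel-volume and μ_eff statistics
- `oaphantom.pipeline` / `oaphantom.cli` — end-to-end generation & CLI

See `docs/methods.md` for the modelling details, parameter defaults, and
known limitations.
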
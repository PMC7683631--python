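# Default pipeline configuration. Values mirror petquant.config.PipelineConfig.
psf_fwhm_mm: 6.5      # assumed reconstructed-image resolution (Gaussian FWHM)
model_sbr: 2.26       # sphere-to-background ratio of the convolution RC model
wall_mm: 1.0          # cold wall thickness of the phantom spheres
peak_voi_ml: 1.0      # SUV_peak VOI volume
interpolation: pchip-logvolume
time_mode: approx     # uptake-time correction form: approx | exact
t0_min: 60.0
vr: 0.53              # apparent volume of distribution
b: 0.313              # blood-SUV decay exponent
grouping_policy: amp_with_wt
exclude_near_treated: false
biopsy_confirmed_only: false
seed: 0
phantom_noise_sd: 0.0
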
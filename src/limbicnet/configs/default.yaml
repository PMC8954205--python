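# Default experiment: the full 10-condition matrix
# ({raw, deblurred sigma_b 1/2, denoised window 3/5} x {whole-brain, cropped})
# on a desk-scale synthetic cohort emulating the 155-control / 66-AD study
# population.  Training hyperparameters follow the reference recipe
# (cross-entropy, Adam, batch 4, 20 epochs, lr 1e-4).

seed: 0
output_dir: runs/default

cohort:
  n_control: 155
  n_ad: 66
  dims: [64, 64, 40]
  subject_sd: 0.05
  noise_model: gaussian
  scanner_profiles:
    - {name: hrrt, blur_sigma: 1.5, noise_sd: 0.12, n_slices: 40, weight: 0.4}
    - {name: hr_plus, blur_sigma: 2.0, noise_sd: 0.10, n_slices: 32, weight: 0.4}
    - {name: accel, blur_sigma: 2.5, noise_sd: 0.10, n_slices: 24, weight: 0.2}

conditions:
  - {name: raw_whole, restoration: {method: none}, cropped: false}
  - {name: raw_crop, restoration: {method: none}, cropped: true}
  - {name: deblur_sigma1_whole, restoration: {method: deblur, sigma_b: 1.0}, cropped: false}
  - {name: deblur_sigma1_crop, restoration: {method: deblur, sigma_b: 1.0}, cropped: true}
  - {name: deblur_sigma2_whole, restoration: {method: deblur, sigma_b: 2.0}, cropped: false}
  - {name: deblur_sigma2_crop, restoration: {method: deblur, sigma_b: 2.0}, cropped: true}
  - {name: denoise_w3_whole, restoration: {method: denoise, mmwf: {window: 3}}, cropped: false}
  - {name: denoise_w3_crop, restoration: {method: denoise, mmwf: {window: 3}}, cropped: true}
  - {name: denoise_w5_whole, restoration: {method: denoise, mmwf: {window: 5}}, cropped: false}
  - {name: denoise_w5_crop, restoration: {method: denoise, mmwf: {window: 5}}, cropped: true}

model:
  input_shape: [64, 64, 40]
  base_channels: 64
  stage_channels: [64, 128]
  lr: 1.0e-4
  batch_size: 4
  epochs: 20

eval:
  cv_k: 3
  mode: cv

crop_regions: [hippocampus, amygdala, thalamus, putamen]
crop_margin: 2
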
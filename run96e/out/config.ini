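[pipeline]
input_path = "run96d/raw.tif"
output_dir = "run96e/out"
voxel_size = [1.0, 1.0, 1.0]
destripe = true
destripe_sigma = 2.0
destripe_levels = null
destripe_wavelet = "db3"
destripe_bidirectional = false
debleach = true
debleach_sigma_um = null
deconvolve = true
deconv_iterations = 10
psf_sigma_xy = 1.0
psf_sigma_z = 2.5
z_downsample = 1
fg_percent = 0.004636411313657407
close_radius = 7
open_radius = 3
min_voxels = 450
close_branches_radius = 1
tolerance = 0.001
coarsen_steps = 2
min_radius_um = null
gold_dir = "run96d/gold"
dist_threshold_um = 8.0
path_tolerance = 0.2
resume = false

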
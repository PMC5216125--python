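# Demo pipeline configuration: three synthetic fields standing in for three
# replicate labelling experiments, membrane-proximal gold placement, and the
# study's measurement parameters (15.5 / 206.1 nm grid spacings, 20 nm band).
out_dir: mitogold_demo_out
rng_seed: 0
n_fields: 3
profiles_per_field: 8
membrane_inset_nm: 15.0
gold_law: membrane_proximal
gold_scale_nm: 10.0
grid_spacing_mitosome_nm: 15.5
grid_spacing_cyto_nucleus_nm: 206.1
band_width_nm: 20.0
rate_window_min: 4.5
epr_frequency_GHz: 9.6359
epr_g_values: [1.89, 1.92, 2.05]
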
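# Demo cohort: 4 subjects, leave-one-out, all three synthesis variants.
n_subjects: 4
seed: 7
grid_size: 48
spacing_mm: 3.0
deformation_mm: 4.0
ct_z_keep_fraction: 0.75
methods: [legacy_t1, roi_t1, roi_t1t2]
scatter_fraction: 0.2
osem_iterations: 3
osem_subsets: 8
run_pet: true
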
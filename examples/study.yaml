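# Full synthetic study: 39 controls / 30 at-risk / 14 FEP, 90 trials each,
# midbrain + right-DLPFC ROIs, 5000-permutation TFCE/FWE group inference.
out_dir: runs/study
seed: 42
grid: reduced
n_perm: 5000
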
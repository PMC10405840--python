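"""Compute regional SUVr and its change between two PET timepoints.

Builds a paired-timepoint PET phantom whose target-region uptake drops from
1.4000 to 1.3748 over a constant unit reference region, then measures the
SUVr change the way a longitudinal amyloid-PET analysis would.
"""

from sonoquant import PETPhantomSpec, compute_suvr, make_pet_pair, suvr_change

spec = PETPhantomSpec(
    regional_means={1: (1.4000, 1.3748), 2: (1.0, 1.0)},  # label: (t0, t1)
    noise_sd=0.0,
    seed=0,
)
baseline, followup, labels, truth = make_pet_pair(spec)

b = compute_suvr(baseline, labels, roi_id=1, reference_ids=(2,))
f = compute_suvr(followup, labels, roi_id=1, reference_ids=(2,))
change = suvr_change(b, f)

print(f"baseline SUVr  : {b.roi_suvr:.4f}   (truth {truth.true_suvr['baseline']:.4f})")
print(f"follow-up SUVr : {f.roi_suvr:.4f}   (truth {truth.true_suvr['followup']:.4f})")
print(f"percent change : {change.percent_change:+.2f} %")
# SUVr is the mean target-region uptake over the mean reference-region uptake
# (the reference plays the role of the whole cerebellum); a negative change
# means the amyloid tracer signal decreased relative to baseline.
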
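"""Extract the 8 tumor-descriptor features from a toy segmentation volume.

Builds a small labeled volume with known descriptor composition, extracts
the 4 mean-presence and 4 ratio features, and prints them.
"""

from elapmc import extract_features
from elapmc.synthetic import HIGH_GRADE, VolumeGenSpec, gen_volume

spec = VolumeGenSpec(dims=(24, 24, 10), n_tumor_slices=6, voxels_per_slice=300)
volume, truth = gen_volume(spec, HIGH_GRADE, seed=0, deterministic=True)

v = extract_features(volume, subject_id="demo-HGG")
print("mean presence (voxels per tumor-bearing slice):")
print(f"  enhancing tC_M={v.tC_M:.2f}  non-enhancing tnC_M={v.tnC_M:.2f}"
      f"  edema Edm_M={v.Edm_M:.2f}  necrosis Nec_M={v.Nec_M:.2f}")
print("composition ratios (sum to 1):")
print(f"  tC_R={v.tC_R:.4f}  tnC_R={v.tnC_R:.4f}"
      f"  Edm_R={v.Edm_R:.4f}  Nec_R={v.Nec_R:.4f}")
print(f"generator's intended composition: {spec.proportions[HIGH_GRADE]}")
# The ratios match the intended high-grade profile exactly in deterministic
# mode: heavy contrast enhancement (0.40) marks the aggressive tumor.
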
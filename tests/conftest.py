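import numpy as np
import pytest

from elapmc import mri_features as mf


def brute_force_features(labels: np.ndarray, label_map: dict) -> dict:
    """Triple-loop reference implementation of the 8 descriptor features.

    Independent of the vectorized extractor: counts voxels and
    tumor-bearing slices by explicit iteration.
    """
    nx, ny, nz = labels.shape
    bg = label_map["background"]
    counts = {role: 0 for role in mf.DESCRIPTOR_ROLES}
    tumor_slices = 0
    for k in range(nz):
        slice_has_tumor = False
        for i in range(nx):
            for j in range(ny):
                v = labels[i, j, k]
                if v != bg:
                    slice_has_tumor = True
                for role in mf.DESCRIPTOR_ROLES:
                    if v == label_map[role]:
                        counts[role] += 1
        if slice_has_tumor:
            tumor_slices += 1
    means = {
        mf.ROLE_TO_STEM[role] + "_M": counts[role] / tumor_slices
        for role in mf.DESCRIPTOR_ROLES
    }
    total = sum(means.values())
    ratios = {k.replace("_M", "_R"): v / total for k, v in means.items()}
    return {**means, **ratios, "z": tumor_slices}


def random_tumor_volume(rng: np.random.Generator, shape=(6, 6, 4)) -> mf.SegmentationVolume:
    """Random label volume guaranteed to contain at least one tumor voxel."""
    while True:
        labels = rng.integers(0, 5, size=shape)
        if np.any(labels != 0):
            return mf.SegmentationVolume(labels)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
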
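"""Quantify per-nucleus protein intensity in two-channel images.

Renders a control and a "treated" image (treated nuclei carry half the
protein intensity), segments nuclei on the nuclear-stain channel, sums the
protein channel per nucleus, and reports relative integrated densities.
"""

import numpy as np

from dtpkit import (
    SimImageTruth,
    gen_nuclei_image,
    integrated_density,
    relative_integrated_density,
    segment_nuclei,
)


def make_image(intensity_scale, seed):
    rng = np.random.default_rng(seed)
    centers, radii = [], []
    while len(centers) < 8:
        rad = float(rng.uniform(7, 11))
        r0 = int(rng.uniform(rad + 2, 198 - rad))
        c0 = int(rng.uniform(rad + 2, 198 - rad))
        if all(
            np.hypot(r0 - r, c0 - c) >= rad + rr + 4
            for (r, c), rr in zip(centers, radii)
        ):
            centers.append((r0, c0))
            radii.append(rad)
    intensities = (rng.uniform(100, 180, 8) * intensity_scale).round().tolist()
    truth = SimImageTruth(
        centers=centers, radii=radii, intensities=intensities,
        shape=(200, 200), noise_sigma=4.0, seed=seed,
    )
    return gen_nuclei_image(truth)


nuc_ctrl, prot_ctrl, _ = make_image(intensity_scale=1.0, seed=1)
nuc_trt, prot_trt, _ = make_image(intensity_scale=0.5, seed=2)

control = integrated_density(segment_nuclei(nuc_ctrl), prot_ctrl)
treated = integrated_density(segment_nuclei(nuc_trt), prot_trt)
treated = relative_integrated_density(treated, control)

print(f"control nuclei: {len(control)}, treated nuclei: {len(treated)}")
print(f"mean control integrated density : {control['integrated_density'].mean():,.0f}")
print(
    "mean treated relative integrated density : "
    f"{treated['relative_integrated_density'].mean():.3f}"
)
# A relative integrated density near 0.5 recovers the planted halving of
# nuclear protein levels in the treated image.
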
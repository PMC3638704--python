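"""Fit the two-compartment model voxelwise on a synthetic phantom.

Builds a small dynamic contrast-enhanced phantom (one malignant and one
benign lesion in an ellipsoidal body), fits the enhancement model in
every body voxel and reports the median fitted back-transfer rate k_ep
per tissue class.  Malignant tissue should show a much faster k_ep than
normal parenchyma — that contrast is what the downstream texture
analysis feeds on.
"""

import numpy as np

from dcetex import Lesion, PhantomSpec, compute_body_mask, fit_volume, generate_phantom

spec = PhantomSpec(
    shape=(32, 32, 10),
    lesions=(
        Lesion((12, 14, 5), (3, 3, 2), "malignant"),
        Lesion((20, 10, 4), (3, 3, 2), "benign"),
    ),
    seed=7,
)
series, malignant, benign, _ = generate_phantom(spec)
body = compute_body_mask(series.baseline)
pseudo = fit_volume(series, body)

for name, mask in (
    ("malignant", malignant),
    ("benign", benign),
    ("normal", body & ~malignant & ~benign),
):
    k = spec.kinetics[name]
    med = np.median(pseudo.k_ep[mask & body])
    print(f"{name:9s}  true k_ep = {k.k_ep:.2f}/min   median fitted = {med:.3f}/min")
print(f"\nfitted volumes: {pseudo.A.shape}, body voxels: {int(body.sum())}")
print("A pseudoimage stores the fitted-curve peak enhancement per voxel.")
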
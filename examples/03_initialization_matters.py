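"""Why automatic near-surface initialization pays off.

Segments the same phantom slice twice: once from the automatically placed
circle (radius one third of the head width, just inside the brain) and once
from a deliberately small, distant circle at the brain centre.  Counts the
iterations each needs to first reach Dice 0.95 against truth.
"""

import numpy as np

from braingac import (
    EvolutionParams,
    InitialContour,
    PhantomSpec,
    auto_initial_contour,
    binarize_head,
    estimate_intensity_range,
    generate_phantom,
    head_threshold,
    init_level_set,
    segment_slice,
)

vol, truth = generate_phantom(PhantomSpec(seed=1))
data = vol.as_float()
z = data.shape[2] // 2
I, truth2d = data[:, :, z], truth.data[:, :, z]
params = EvolutionParams()


def iterations_to_dice(phi0, target=0.95):
    hits = []

    def watch(it, mask):
        tp = np.count_nonzero(mask & truth2d)
        if not hits and 2 * tp / (mask.sum() + truth2d.sum()) >= target:
            hits.append(it)

    segment_slice(I, phi0, params, on_iteration=watch)
    return hits[0] if hits else None


head = binarize_head(I, head_threshold(estimate_intensity_range(data), 3.0))
close = auto_initial_contour(head, "axial")
rows, cols = np.nonzero(truth2d)
width = cols.max() - cols.min()
far = InitialContour(((rows.min() + rows.max()) / 2, (cols.min() + cols.max()) / 2),
                     width / 10, (width // 10, width // 10), "axial")

n_close = iterations_to_dice(init_level_set(close, I.shape, 1.0))
n_far = iterations_to_dice(init_level_set(far, I.shape, 1.0))
print(f"automatic circle (r={close.radius:.0f} voxels): Dice>=0.95 after {n_close} iterations")
print(f"distant small circle (r={far.radius:.0f} voxels): Dice>=0.95 after {n_far} iterations")
# the near-surface contour converges several times faster — initialization
# close to the target boundary is what makes the method cheap in practice.
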
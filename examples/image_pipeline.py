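"""Image-based labeling-index pipeline on one rendered chip.

Renders a two-channel fluorescence field (DAPI: all nuclei; BrdU: labeled
subset) from simulated ground truth, re-detects the nuclei from the
pixels, matches the channels to assign labels, and compares the resulting
zone NLI against the NLI computed directly from the ground-truth records.
"""

import numpy as np

from dynsurf import PatternSpec, SimulationConfig, compute_nli, records_from_images
from dynsurf.simulate import gen_pattern_nuclei, render_nuclei_images

pattern = PatternSpec(shape="circle", radius=55.0, zone_width=55.0)
config = SimulationConfig(
    seed=1,
    pattern=pattern,
    n_chips=1,
    nuclei_per_zone={0: 45, 1: 70, 2: 80},
    labeling_probability={0: 0.275, 1: 0.45, 2: 0.65},
    min_separation=12.0,  # keep spots optically resolvable (3 x spot sigma)
)
records = gen_pattern_nuclei(config)
image = render_nuclei_images(
    records, pixel_size=1.0, spot_sigma=4.0, amplitude=1000.0, noise_sd=10.0,
    rng=np.random.default_rng(1),
)
result = records_from_images(
    image.dapi, image.brdu, pixel_size=1.0, sigma=4.0, origin=image.origin
)
print(f"ground truth: {len(records)} nuclei, {int(records['labeled'].sum())} labeled")
print(f"from images : {len(result.records)} nuclei, "
      f"{int(result.records['labeled'].sum())} labeled "
      f"({result.n_unmatched_brdu} unmatched BrdU spots)")

truth_nli = compute_nli(records, pattern)
image_nli = compute_nli(result.records, pattern)
for (_, t), (_, m) in zip(truth_nli.iterrows(), image_nli.iterrows()):
    print(f"zone {int(t['zone'])}: truth {t['nli_pct']:5.1f}%  image {m['nli_pct']:5.1f}%")

# With well-separated spots and high signal-to-noise, the image path
# reproduces the record-based NLI to within a fraction of a point, so
# both input routes feed the same downstream statistics.
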
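"""'Step zero' prefilters: shrink the covering problem before running it.

Two optional reductions applied before the heuristic: drop loads below a
magnitude of interest, and drop loads already accounted for by a committed
load case (stumbling is the classic example — enormous magnitude, known
direction).
"""

import numpy as np

from majorload import (Cone, cover, generate_daily_activity_dataset,
                       prefilter_by_magnitude, remove_precovered, unit)

dataset = generate_daily_activity_dataset(seed=1)
print(f"full collection: {len(dataset)} vectors -> "
      f"{len(cover(dataset))} major loads")

strong = prefilter_by_magnitude(dataset, threshold=100.0)  # keep > 100 BW%
print(f"above 100 BW%:   {len(strong)} vectors -> "
      f"{len(cover(strong))} major loads")

# a committed stumbling-style load case: huge magnitude along the dominant
# superior-medial direction, with its own 15-degree sector
stumble = Cone(unit(np.array([228.0, -207.0, 1803.0])), 15.0)
remainder = remove_precovered(strong, [stumble], magnitudes=[870.0])
print(f"minus stumbling: {len(remainder)} vectors -> "
      f"{len(cover(remainder))} major loads")

print("\nEach filter removes vectors a committed load case already "
      "envelops, so the heuristic only spends cones on what is left.")
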
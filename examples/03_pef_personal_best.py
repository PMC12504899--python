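"""Peak-flow cleaning, personal-best estimation and traffic-light zoning.

Personal best is the highest session maximum not exceeding the 95th
percentile of a participant's session maxima — a robust cap against entry
errors and isolated super-maximal efforts. Sessions are then zoned green
(>=80% of personal best), yellow (50-79%) or red (<50%).
"""

import numpy as np

from vbmon.pef import personal_best, relative_pef, session_max_pef

rng = np.random.default_rng(0)
session_maxes = [session_max_pef(rng.normal(420, 25, 3)) for _ in range(30)]
session_maxes.append(session_max_pef([980.0, 410.0, 1200.0]))  # 1200 dropped as error

pb = personal_best(session_maxes)
print(f"session maxima: n={len(session_maxes)}, max={max(session_maxes):.0f} L/min")
print(f"personal best (95th-percentile-capped maximum): {pb:.0f} L/min")

for value in (0.95 * pb, 0.70 * pb, 0.40 * pb, 0.15 * pb):
    pct, zone = relative_pef(value, pb)
    print(f"  reading {value:6.0f} L/min -> {pct:5.1f}% of personal best -> {zone or 'excluded (implausible)'}")

print(
    "\nThe 980 L/min effort is capped out of the personal best, so ordinary"
    "\nsessions are not all pushed into the yellow zone by one outlier."
)
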
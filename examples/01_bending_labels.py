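"""Bending labels of an implanted electrode.

Builds a small bent trajectory, computes the per-point regression labels
(local displacement lu, bending direction eb, global displacement gu),
and verifies the defining identity v + lu = eb.
"""

import numpy as np

from seegbend import Trajectory, compute_labels, rigid_trajectory

# a 1 mm-spaced electrode that starts along +z and drifts in +y
points = [[0, 0, 0], [0, 0, 1], [0, 0.6, 1.8]]
implanted = Trajectory(points, kind="implanted")
rigid = rigid_trajectory(entry=(0, 0, 0), bolt_direction=(0, 0, 1), depth=2)

labels = compute_labels(implanted, rigid)
print("travel direction v :", labels.v_hat[0])
print("local displacement lu (mm):", labels.lu[0])
print("bending direction eb:", labels.eb_hat[0], "| norm",
      np.linalg.norm(labels.eb_hat[0]))
print("global displacement gu (mm):", labels.gu[0])
print("identity |v + lu - eb| =",
      np.abs(labels.v_hat[0] + labels.lu[0] - labels.eb_hat[0]).max())

# lu is the millimetre offset of the next point from a 1 mm straight-ahead
# projection; eb is the unit step direction toward the next point. A zero
# lu (or eb = v) means the electrode did not bend at this point.
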
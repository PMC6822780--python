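"""Why saturation concentrations are not constants in heterotypic systems.

Uses the tie-line geometry inside an elliptical binodal: the measured
dilute-phase concentration [A]_Sol depends on the tie-line slopes, so the
classic fixed-c_sat picture only survives when tie lines are vertical.
"""

import numpy as np

from sslattice.phase import EllipseFit, tie_line_dilute_scan

# an elliptical two-phase loop in the ([B], [A]) plane
ellipse = EllipseFit(center=(0.0, 0.0), semi_axes=(2.0, 0.8), theta=0.5,
                     residual=0.0)
a_grid = np.linspace(-2.0, 2.0, 9)

for slope in ("horizontal", "vertical", 0.4):
    curves = tie_line_dilute_scan(ellipse, slope, [0.0], a_grid)
    vals = ", ".join(f"{v:+.2f}" for v in curves[0.0])
    print(f"tie lines {str(slope):>10}:  [A]_Sol = {vals}")

# horizontal tie lines: [A]_Sol rises linearly with [A] inside the loop;
# vertical ones: a flat plateau (the classic saturation concentration);
# oblique ones: nonlinear variation.  Only the vertical case reproduces a
# concentration-independent c_sat.
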
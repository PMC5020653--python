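"""Sub-pixel vesicle contour detection on a synthetic confocal slice.

Renders a noisy ring image (SNR 8) with known centre and radius, then runs
the contour pipeline: radial rays from a rough centre guess, arg-max per
ray, sub-pixel refinement by linear regression on the discrete derivative,
and an algebraic least-squares circle fit.  Centre and radius come back to
better than a tenth of a pixel.
"""

import numpy as np

from memcurv import render_vesicle_image, track_vesicle

true_centre = (127.4, 129.1)
true_R = 50.0
img, truth = render_vesicle_image(R=true_R, centre=true_centre, snr=8.0, seed=5)

fit = track_vesicle(img, centre_guess=(124.0, 126.0))
print(f"true   centre ({true_centre[0]:.2f}, {true_centre[1]:.2f}), R {true_R:.2f} px")
print(f"fitted centre ({fit.centre[0]:.2f}, {fit.centre[1]:.2f}), R {fit.radius:.2f} px")
print(f"errors: centre {np.hypot(fit.centre[0] - true_centre[0], fit.centre[1] - true_centre[1]):.3f} px, "
      f"radius {abs(fit.radius - true_R):.3f} px")
print(f"{fit.n_rays - fit.n_dropped}/{fit.n_rays} rays used, residual rms {fit.residual_rms:.3f} px")
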
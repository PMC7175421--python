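"""Generate a synthetic iSCAT movie of myosin II filaments with ground truth.

Builds a small 635-nm scene, renders it with PSF blur, static background
fields and shot noise, and prints summary statistics of the movie and the
underlying truth table.
"""

import numpy as np

from myofil.simulate import (MyosinSceneConfig, OpticsConfig, render_movie,
                             simulate_trajectories)

optics = OpticsConfig(fov_px=(128, 128))          # 635 nm, 31.8 nm/px, 25 fps
myosin = MyosinSceneConfig.for_wavelength(635, arrival_rate_per_s=0.5)
truth = simulate_trajectories(None, myosin, n_frames=250, dt_s=optics.dt_s,
                              seed=7, fov_um=optics.fov_um)
stack = render_movie(truth, optics, seed=7)

print(f"rendered {stack.n_frames} frames of {stack.frame_shape} px "
      f"({optics.fov_um[0]:.1f} x {optics.fov_um[1]:.1f} um)")
print(f"{len(truth.particles)} myosin filaments landed; "
      f"{sum(p.censored for p in truth.particles)} overlap the recording end")
print(f"darkest pixel contrast: {stack.frames.min():.4f} "
      f"(single-filament calibration is -0.017 +- 0.006 at 635 nm)")
print(f"background noise s.d.: {np.median(np.std(stack.frames, axis=0)):.4f}")
# stack.save_tiff("scene.tif"); truth.save_csv("truth.csv")
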
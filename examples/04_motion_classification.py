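"""Directed/random motion segmentation and torsional stiffness.

Simulates bound myosin II filaments alternating diffusive and processive
motion, segments each track against the diffusive envelope, and infers the
effective torsional spring constant from orientation-velocity angles during
directed runs.
"""

import numpy as np

from myofil import motion
from myofil.simulate import MyosinSceneConfig, simulate_trajectories

cfg = MyosinSceneConfig(
    arrival_rate_per_s=2.0, dwell_mixture=((1.0, 20.0),),
    p_directed=0.5, v_directed_um_s=(0.46, 0.0),
    angular_stiffness_pN_nm=9.0)
truth = simulate_trajectories(None, cfg, n_frames=300, dt_s=0.2, seed=5,
                              fov_um=(30.0, 30.0))

D_ref = cfg.D_random_um2_s
ratios, alphas = [], []
for p in truth.particles:
    if p.n_frames < 10:
        continue
    xy = np.column_stack([p.x_um, p.y_um])
    segs = motion.classify_motion(xy, 0.2, D_ref, track_id=p.id)
    ratios.append(motion.directed_time_ratio(segs))
    for s in segs:
        if s.state == "directed":
            stats = motion.alpha_angles(xy[s.start:s.end + 1],
                                        p.theta_rad[s.start:s.end + 1])
            alphas.extend(stats.alpha_rad)

alphas = np.array(alphas)
K_tor = motion.torsional_stiffness(float(np.mean(alphas ** 2)))
print(f"{len(ratios)} tracks; mean directed-time ratio "
      f"{np.mean(ratios):.2f} (generator alternates ~50% directed)")
print(f"orientation-velocity angle spread during runs: "
      f"{np.degrees(np.std(alphas)):.1f} deg")
print(f"inferred K_tor = {K_tor:.1f} pN nm/rad^2 (generator used 9.0) —")
print("the angular fluctuation variance times K_tor equals k_B T")
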
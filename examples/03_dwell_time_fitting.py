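"""Truncated maximum-likelihood fitting of myosin dwell-time mixtures.

Simulates dwell times from the triple-exponential mixture typical of
myosin II filament binding (fast single-head events, one-sided and
two-sided multi-head binding), discards events below the 0.3-s detection
limit, and refits with the truncation-aware likelihood.
"""

from myofil import kinetics
from myofil.simulate import sample_dwell_times

mixture = [(0.55, 0.34), (0.35, 2.26), (0.10, 10.9)]   # (fraction, tau_s)
dwells = sample_dwell_times(mixture, 14_016, seed=3)
observed = dwells[dwells >= 0.3]                       # detection limit

fit = kinetics.fit_exp_mixture(observed, k=3, t_min_s=0.3, seed=3)
kinetics.bootstrap_ci(observed, fit, B=200, seed=3)

print(f"fitted {fit.k}-component truncated mixture on n={fit.n} dwells:")
for i, (a, tau) in enumerate(zip(fit.fractions, fit.taus)):
    lo, hi = fit.ci95[f"tau{i}"]
    print(f"  component {i}: fraction {a:.2f}, "
          f"tau = {tau:.2f} s  [95% CI {lo:.2f}-{hi:.2f}]")
print("(generator used taus 0.34, 2.26, 10.9 s; the truncated likelihood")
print(" recovers the fast component even though events < 0.3 s are unseen)")

sel = kinetics.select_model(observed, k_max=3, t_min_s=0.3)
print(f"BIC model selection over k = 1..3 chooses k = {sel['k_best']}")
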
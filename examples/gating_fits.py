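"""Boltzmann, exponential and Hill fits on synthetic recordings.

Forward-simulates a steady-state activation curve, an activation time
course and a concentration–binding curve at the wildtype parameter
values, adds measurement noise, and fits each model back.  Printed
values should recover the generating parameters within the noise.
"""

from hcnflex.fits import (fit_activation_exponential, fit_boltzmann,
                          fit_hill)
from hcnflex.synth import (generate_activation_curve,
                           generate_activation_trace,
                           generate_binding_curve)

curve, truth = generate_activation_curve(V_half=-119.6, z_delta=4.0,
                                         noise_sd=0.02, seed=5)
bf = fit_boltzmann(curve)
print("steady-state activation (Boltzmann):")
print(f"  V_1/2 = {bf.V_half:7.1f} ± {bf.V_half_se:.1f} mV   "
      f"(truth {truth['V_half']})")
print(f"  zδ    = {bf.z_delta:7.2f} ± {bf.z_delta_se:.2f}      "
      f"(truth {truth['z_delta']})")
# V_1/2 is the voltage of half-maximal activation; zδ the effective
# gating charge governing the steepness of the relation

trace, truth = generate_activation_trace(tau=120.0, delay=20.0,
                                         noise_sd=0.01, seed=6)
ef = fit_activation_exponential(trace)
print("activation kinetics (single exponential after a delay):")
print(f"  τ = {ef.tau:6.1f} ± {ef.tau_se:.1f} ms   (truth {truth['tau']}, "
      f"delay estimate {ef.delay_used:.0f} ms)")

binding, truth = generate_binding_curve(BC50=0.51, H_b=1.4,
                                        noise_sd=0.02, seed=7)
hf = fit_hill(binding)
print("ligand binding (Hill):")
print(f"  BC50 = {hf.BC50:5.2f} ± {hf.BC50_se:.2f} µM   (truth {truth['BC50']})")
print(f"  H_b  = {hf.H_b:5.2f} ± {hf.H_b_se:.2f}      (truth {truth['H_b']})")
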
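"""Propagate rate-constant standard errors into the affinity.

KD = kd/ka, and its standard error combines the relative errors of the
two rate constants in quadrature:

    dKD = KD * sqrt((dka/ka)^2 + (dkd/kd)^2)
"""

from titrofit import propagate_kd

ka, d_ka = 1.81e3, 8.73      # 1/(M*s)
kd, d_kd = 1.19e-4, 8.04e-7  # 1/s

kD, d_kD = propagate_kd(ka, kd, d_ka, d_kd)
print(f"ka = {ka:.2E} ± {d_ka:.2E} 1/(M*s)")
print(f"kd = {kd:.2E} ± {d_kd:.2E} 1/s")
print(f"KD = {kD:.3E} ± {d_kD:.3E} M")
# A ~66 nM affinity known to better than 1%: both relative rate errors
# are small, so the relative error on KD is small too.
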
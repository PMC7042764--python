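"""The transient Cormack-Jolly-Seber likelihood on small worked examples.

Walks through the marginalization over residency and alive states for
hand-checkable capture histories, then verifies probability normalization
over every possible outcome.
"""

import numpy as np

from birdipm import cmr_model as cm

pi, phi, p, rho = 0.5, 0.5, 0.5, 0.7

print("History (1,1): marked then recaptured - only a surviving resident can "
      "produce this.")
ll = cm.cjs_marginal_loglik([1, 1], pi, [phi], [p])
print(f"  log L = {ll:.4f};  pi*phi*p = {pi*phi*p}  (exp(log L) = {np.exp(ll):.4f})\n")

print("History (1,0): never seen again - transient, or dead, or missed:")
ll = cm.cjs_marginal_loglik([1, 0], pi, [phi], [p])
manual = (1 - pi) + pi * ((1 - phi) + phi * (1 - p))
print(f"  log L = {ll:.4f};  (1-pi) + pi*[(1-phi) + phi(1-p)] = {manual}\n")

print("Joint with the residency observation r (r=1 can only come from a "
      "resident, P(r=1) = pi*rho):")
for r in (0, 1):
    ll = cm.transient_cjs_joint_loglik([1, 0], r, pi, rho, [phi], [p])
    print(f"  r={r}: joint log L = {ll:.4f}  (P = {np.exp(ll):.4f})")

print("\nNormalization over all T=3 outcomes (8 histories x 2 residency obs):")
total = 0.0
for tail in [(0, 0), (0, 1), (1, 0), (1, 1)]:
    for r in (0, 1):
        ll = cm.transient_cjs_joint_loglik(
            np.array((1,) + tail), r, pi, rho, [phi, phi], [p, p]
        )
        if np.isfinite(ll):
            total += np.exp(ll)
print(f"  summed probability = {total:.12f}  (must be exactly 1)")
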
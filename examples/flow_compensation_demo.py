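"""Why first-moment nulling matters: flow phase of moving spins.

A spin at position x0 moving with velocity v through the preparation
gradients acquires the phase phi = gamma*(M0*x0 + M1*v).  An M0-only
compensated preparation leaves the velocity term and dephases flowing
blood (the signal voids seen after diffusion preparations); nulling M1 as
well removes the corruption.
"""

from mcdpmrf import ConstraintSpec, bvalue, flow_phase, optimize_prep, scale_to_b

w_mc0 = optimize_prep(spec=ConstraintSpec(null_m1=False, maxwell=False)).waveform
w_mc1 = optimize_prep(spec=ConstraintSpec()).waveform
b = min(bvalue(w_mc0), bvalue(w_mc1))
w_mc0, w_mc1 = scale_to_b(w_mc0, b), scale_to_b(w_mc1, b)
print(f"both preparations scaled to b = {b:.0f} s/mm^2")

print(f"{'velocity (m/s)':>16} {'phi M0-only (rad)':>20} {'phi M0+M1 (rad)':>18}")
for v in (0.0, 0.1, 0.3, 1.0):
    p0 = flow_phase(w_mc0, x0=0.0, v=v)
    p1 = flow_phase(w_mc1, x0=0.0, v=v)
    print(f"{v:16.1f} {p0:20.2f} {p1:18.2e}")
# Blood moves at 0.1-1 m/s: the M0-only preparation accrues many radians
# of velocity-dependent phase (intravoxel spread -> signal void), while
# the M0+M1-nulled design stays at numerical zero for any velocity.
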
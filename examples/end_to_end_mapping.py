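"""End-to-end T1/T2/ADC mapping on a digital phantom.

Simulates the 480-shot tiny-golden-angle radial acquisition of a
three-tissue phantom, reconstructs the singular-coefficient images with
the density-compensated subspace solver, matches voxels against a coarse
dictionary and prints the per-region recovered parameters.
"""

import numpy as np

from mcdpmrf import (
    ReconConfig,
    build_dictionary,
    compress,
    default_schedule,
    demo_grids,
    make_phantom,
    make_trajectory,
    match,
    simulate_acquisition,
    voronoi_dcf,
)
from mcdpmrf.recon import lowrank_inversion

schedule = default_schedule()
phantom = make_phantom("sectors", 64, n_coils=1)
traj = make_trajectory(64, n_spokes=schedule.n_readouts)
kspace = simulate_acquisition(phantom, schedule, traj)
print(f"simulated {traj.n_spokes} spokes x {traj.samples_per_spoke} samples")

d = compress(build_dictionary(schedule, *demo_grids()))
x = lowrank_inversion(
    kspace.data, traj, phantom.coil_maps, d.basis, ReconConfig(), dcf=voronoi_dcf(traj)
)
params, _, corr = match(x.reshape(d.basis.shape[1], -1).T, d)

t1_map = params[:, 0].reshape(64, 64)
t2_map = params[:, 1].reshape(64, 64)
adc_map = params[:, 2].reshape(64, 64)
print(f"{'region':>8} {'true T1/T2/ADC':>20} {'median recovered':>22}")
for lab, tp in sorted(phantom.tissues.items()):
    m = phantom.label_image == lab
    rec = (np.median(t1_map[m]), np.median(t2_map[m]), np.median(adc_map[m]))
    print(
        f"{lab:>8} {tp.t1:7.0f}/{tp.t2:4.0f}/{tp.adc:3.1f}    "
        f"{rec[0]:9.0f}/{rec[1]:4.0f}/{rec[2]:3.1f}"
    )
# Each region's median matched tuple should equal its ground truth; the
# maps' voxelwise exactness is limited only by edge voxels, where radial
# sampling cannot encode the unsampled k-space corners.
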
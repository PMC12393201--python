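"""Digital phantoms, coil maps, acquisition simulation and flow corruption."""

import numpy as np
import pytest

from mcdpmrf import (
    FlowModel,
    SequenceSchedule,
    SubspaceRadialOperator,
    TissueParams,
    in_vivo_grids,
    load_kspace,
    make_coil_maps,
    make_phantom,
    make_trajectory,
    save_kspace,
    simulate_acquisition,
    simulate_fingerprint,
)


@pytest.fixture(scope="module")
def toy_schedule():
    """Short two-block schedule with one diffusion preparation."""
    return SequenceSchedule(
        block_preps=(
            ("t2prep", {"dur": 50.0}),
            ("diffprep", {"dur": 50.0, "b": 600.0}),
        )
    )


class TestPhantoms:
    @pytest.mark.parametrize("kind", ["tubes_t1mes", "tubes_pvp", "liver", "sectors"])
    def test_determinism(self, kind):
        a = make_phantom(kind, 64, seed=3)
        b = make_phantom(kind, 64, seed=3)
        assert np.array_equal(a.label_image, b.label_image)
        assert np.array_equal(a.coil_maps, b.coil_maps)

    def test_pvp_tubes_share_relaxation_times(self):
        ph = make_phantom("tubes_pvp", 64)
        t1s = {tp.t1 for tp in ph.tissues.values()}
        t2s = {tp.t2 for tp in ph.tissues.values()}
        assert t1s == {700.0} and t2s == {40.0}
        adcs = sorted(tp.adc for tp in ph.tissues.values())
        assert adcs[0] >= 0.3 and adcs[-1] <= 2.0

    @pytest.mark.parametrize("kind", ["tubes_t1mes", "tubes_pvp", "liver"])
    def test_tissues_inside_dictionary_hull(self, kind):
        t1g, t2g, adcg = in_vivo_grids()
        ph = make_phantom(kind, 64)
        for tp in ph.tissues.values():
            assert t1g[0] <= tp.t1 <= t1g[-1]
            assert t2g[0] <= tp.t2 <= t2g[-1]
            assert adcg[0] <= tp.adc <= adcg[-1]

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            make_phantom("brain", 64)

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            make_phantom("liver", 16)


class TestCoilMaps:
    def test_single_coil_is_uniform(self):
        maps = make_coil_maps(48, 1)
        assert np.allclose(maps, 1.0)

    def test_determinism(self):
        assert np.array_equal(make_coil_maps(48, 4, seed=5), make_coil_maps(48, 4, seed=5))

    def test_sum_of_squares_floor_and_smoothness(self):
        maps = make_coil_maps(64, 6, seed=2)
        sos = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
        assert sos.min() >= 0.1
        grad = np.abs(np.diff(sos, axis=0)).max()
        assert grad < 0.05  # smooth on the pixel scale


class TestAcquisition:
    def test_single_tissue_matches_forward_model(self, toy_schedule):
        """Uniform-coil, single-tissue phantom: the simulated spokes equal
        the subspace forward model driven by the analytic contrast series."""
        n = 32
        label = np.zeros((n, n), int)
        label[8:24, 8:24] = 1
        from mcdpmrf.phantom import DigitalPhantom

        ph = DigitalPhantom(
            label_image=label,
            tissues={1: TissueParams(800.0, 40.0, 1.0)},
            coil_maps=np.ones((1, n, n), complex),
        )
        traj = make_trajectory(n, n_spokes=toy_schedule.n_readouts)
        k = simulate_acquisition(ph, toy_schedule, traj)
        fp = simulate_fingerprint(toy_schedule, TissueParams(800.0, 40.0, 1.0))
        op = SubspaceRadialOperator(traj, ph.coil_maps, fp[:, None])
        expected = op.forward((label == 1).astype(complex)[None])
        assert np.allclose(k.data, expected)

    def test_noise_determinism_and_effect(self, toy_schedule):
        ph = make_phantom("liver", 32)
        traj = make_trajectory(32, n_spokes=toy_schedule.n_readouts)
        a = simulate_acquisition(ph, toy_schedule, traj, noise_sigma=1e-3, seed=5)
        b = simulate_acquisition(ph, toy_schedule, traj, noise_sigma=1e-3, seed=5)
        c = simulate_acquisition(ph, toy_schedule, traj, noise_sigma=0.0)
        assert np.array_equal(a.data, b.data)
        assert not np.allclose(a.data, c.data)

    def test_flow_requires_waveform(self, toy_schedule):
        ph = make_phantom("liver", 32)
        flow = FlowModel(velocity_image=np.zeros((32, 32)))
        with pytest.raises(ValueError):
            simulate_acquisition(ph, toy_schedule, flow=flow)


class TestFlowCorruption:
    def test_m1_nulled_prep_leaves_data_unchanged(self, toy_schedule, opt_results):
        """With the fully compensated preparation the flow phase vanishes,
        so flow-enabled and flow-disabled acquisitions are identical."""
        ph = make_phantom("liver", 32)
        vel = np.where(ph.label_image == 2, 0.2, 0.0)
        traj = make_trajectory(32, n_spokes=toy_schedule.n_readouts)
        w = opt_results["mc0_mc1_mx"].waveform
        k_flow = simulate_acquisition(
            ph, toy_schedule, traj, prep_waveform=w,
            flow=FlowModel(velocity_image=vel),
        )
        k_still = simulate_acquisition(ph, toy_schedule, traj)
        assert np.allclose(k_flow.data, k_still.data, atol=1e-12)

    def test_m0_only_prep_attenuates_vessel_signal(self, toy_schedule, opt_results):
        """An M0-only compensated preparation of equal b-value dephases
        moving voxels: the vessel image magnitude after zero-filled
        reconstruction drops relative to the M1-nulled preparation."""
        from mcdpmrf import scale_to_b, bvalue, voronoi_dcf

        ph = make_phantom("liver", 32)
        vel = np.where(ph.label_image == 2, 0.25, 0.0)
        traj = make_trajectory(32, n_spokes=toy_schedule.n_readouts)
        w_mc1 = opt_results["mc0_mc1_mx"].waveform
        w_mc0 = opt_results["mc0"].waveform
        b_common = min(bvalue(w_mc1), bvalue(w_mc0))
        w_mc1 = scale_to_b(w_mc1, b_common)
        w_mc0 = scale_to_b(w_mc0, b_common)

        dcf = voronoi_dcf(traj)
        fp = simulate_fingerprint(toy_schedule, ph.tissues[1])
        basis = (fp / np.linalg.norm(fp))[:, None]
        op = SubspaceRadialOperator(traj, ph.coil_maps, basis)

        mags = {}
        for name, w in (("mc1", w_mc1), ("mc0", w_mc0)):
            k = simulate_acquisition(
                ph, toy_schedule, traj, prep_waveform=w,
                flow=FlowModel(velocity_image=vel),
            )
            img = op.adjoint(k.data, weights=dcf)[0]
            mags[name] = np.mean(np.abs(img[ph.label_image == 2]))
        assert mags["mc0"] < 0.9 * mags["mc1"]


def test_kspace_io_roundtrip(tmp_path, toy_schedule):
    ph = make_phantom("liver", 32)
    traj = make_trajectory(32, n_spokes=toy_schedule.n_readouts)
    k = simulate_acquisition(ph, toy_schedule, traj, noise_sigma=1e-3, seed=9)
    path = tmp_path / "k.h5"
    save_kspace(k, path)
    k2 = load_kspace(path)
    assert np.array_equal(k2.data, k.data)
    assert np.allclose(k2.traj.angles, k.traj.angles)
    assert k2.noise_sigma == k.noise_sigma
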
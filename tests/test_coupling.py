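import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gnmpath import (
    ToySpec,
    build_model,
    find_peaks,
    make_chain,
    total_coupling_averaged,
    total_coupling_single,
)
from gnmpath.coupling import station_grid, profile_to_tsv
from gnmpath.synthetic import cluster_residue_ids

from conftest import chain_from_coords, random_chain


def total_coupling_double_loop(model, mode_rank=1, mode_weight="lambda"):
    """Independent oracle: the literal double loop over residue pairs."""
    lam, u = model.fastest_mode(mode_rank)
    weight = {"lambda": lam, "inv-lambda": 1.0 / lam, "none": 1.0}[mode_weight]
    n = len(u)
    ct = np.zeros(n)
    for i in range(n):
        for j in range(n):
            ct[i] += (u[i] - u[j]) ** 2
    ct *= weight
    return ct - ct.min()


class TestTotalCouplingSingle:
    def test_symmetric_ring_gives_zero_vector(self, ring12):
        model = build_model(ring12, 7.0)
        ct = total_coupling_single(model)
        np.testing.assert_allclose(ct, np.zeros(12), atol=1e-10)

    @pytest.mark.parametrize("mode_weight", ["lambda", "inv-lambda", "none"])
    def test_identity_matches_double_loop(self, mode_weight):
        chain = random_chain(25, seed=1, box=14.0)
        model = build_model(chain, 7.0)
        np.testing.assert_allclose(
            total_coupling_single(model, mode_weight=mode_weight),
            total_coupling_double_loop(model, mode_weight=mode_weight),
            atol=1e-10,
        )

    def test_clustered_maximum_at_high_coordination_residue(self, clustered40):
        model = build_model(clustered40, 7.0)
        ct = total_coupling_single(model)
        degrees = np.diag(model.kirchhoff)
        cluster = set(cluster_residue_ids(ToySpec(kind="clustered", n=40, seed=3)))
        top = int(clustered40.res_ids[np.argmax(ct)])
        assert top in cluster
        # the fast mode localizes where coordination is highest
        assert degrees[np.argmax(ct)] >= np.median(degrees)

    def test_nonnegative(self):
        chain = random_chain(20, seed=2, box=13.0)
        ct = total_coupling_single(build_model(chain, 7.0))
        assert ct.min() == 0.0
        assert (ct >= 0).all()

    def test_sign_flip_invariance(self):
        chain = random_chain(20, seed=3, box=13.0)
        model = build_model(chain, 7.0)
        lam, u = model.fastest_mode()
        n = len(u)
        direct = lam * (n * u**2 + 1.0 - 2.0 * u * u.sum())
        flipped_u = -u
        flipped = lam * (n * flipped_u**2 + 1.0 - 2.0 * flipped_u * flipped_u.sum())
        np.testing.assert_allclose(direct - direct.min(), flipped - flipped.min())

    def test_mode_rank_out_of_range(self):
        chain = random_chain(10, seed=4, box=10.0)
        model = build_model(chain, 7.0)
        with pytest.raises(ValueError, match="mode_rank"):
            total_coupling_single(model, mode_rank=model.n)

    def test_cross_module_consistency_with_distance_fluctuation(self):
        # C_T row equals the lambda-weighted rank-1 distance-fluctuation row sum
        chain = random_chain(22, seed=5, box=13.0)
        model = build_model(chain, 7.0)
        lam, _ = model.fastest_mode()
        rowsum = model.distance_fluctuation([model.n - 1]).sum(axis=1) * lam**2
        np.testing.assert_allclose(
            total_coupling_single(model), rowsum - rowsum.min(), atol=1e-10
        )


class TestStationGrid:
    def test_default_stations(self):
        np.testing.assert_allclose(
            station_grid(), [6.9, 6.975, 7.05, 7.125, 7.2]
        )

    def test_single_station(self):
        np.testing.assert_allclose(station_grid(7.0, 7.3, 1), [7.0])

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            station_grid(7.2, 6.9, 5)


class TestTotalCouplingAveraged:
    def test_single_station_equals_normalized_single(self, clustered40):
        profile = total_coupling_averaged(clustered40, 7.0, 7.3, n_stations=1)
        ct = total_coupling_single(build_model(clustered40, 7.0))
        np.testing.assert_allclose(profile.averaged_ct, ct / ct.max(), atol=1e-12)

    def test_identical_stations_equal_single_station(self, clustered40):
        avg = total_coupling_averaged(clustered40, 7.0, 7.4, n_stations=5)
        one = total_coupling_averaged(clustered40, 7.0, 7.4, n_stations=1)
        # not identical (different stations) but max is normalized in both
        assert avg.averaged_ct.max() == 1.0
        assert one.averaged_ct.max() == 1.0

    def test_averaging_over_duplicate_station_values(self, clustered40):
        one = total_coupling_averaged(clustered40, 7.0, 7.3, n_stations=1)
        # averaging n copies of the same station must reproduce the profile
        per = one.per_station_ct[0]
        stacked = np.vstack([per, per, per])
        normed = stacked / stacked.max(axis=1, keepdims=True)
        averaged = normed.mean(axis=0)
        np.testing.assert_allclose(averaged / averaged.max(), one.averaged_ct)

    def test_profile_invariants(self, clustered40):
        profile = total_coupling_averaged(clustered40)
        assert profile.averaged_ct.max() == 1.0
        assert profile.averaged_ct.min() >= 0.0
        assert (profile.per_station_ct >= 0).all()
        assert profile.hub == int(
            profile.residue_ids[np.argmax(profile.averaged_ct)]
        )

    def test_hub_stable_under_rigid_motion(self, clustered40):
        profile = total_coupling_averaged(clustered40)
        rot = Rotation.from_euler("xyz", [31, -47, 103], degrees=True).as_matrix()
        moved = chain_from_coords(
            clustered40.coords @ rot.T + np.array([11.0, -22.0, 5.0]),
            res_ids=clustered40.res_ids,
        )
        assert total_coupling_averaged(moved).hub == profile.hub

    def test_hub_stable_under_renumbering(self, clustered40):
        profile = total_coupling_averaged(clustered40)
        shifted = chain_from_coords(
            clustered40.coords, res_ids=clustered40.res_ids + 100
        )
        assert total_coupling_averaged(shifted).hub == profile.hub + 100

    def test_disconnected_station_warns_and_proceeds(self, caplog):
        coords = np.vstack(
            [
                [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [7.6, 3.8, 0]],
                [[60, 0, 0], [63.8, 0, 0], [67.6, 0, 0], [67.6, 3.8, 0]],
            ]
        )
        chain = chain_from_coords(coords)
        with caplog.at_level("WARNING"):
            profile = total_coupling_averaged(chain)
        assert any("disconnected" in r.message for r in caplog.records)
        assert profile.averaged_ct.max() == 1.0


class TestFindPeaks:
    def test_flat_zero_profile_empty(self, ring12):
        profile = total_coupling_averaged(ring12)
        assert find_peaks(profile) == []

    def test_monotone_profile_single_terminal_peak(self, clustered40):
        profile = total_coupling_averaged(clustered40)
        monotone = profile.averaged_ct.copy()
        monotone[:] = np.linspace(0.0, 1.0, profile.n)
        object.__setattr__(profile, "averaged_ct", monotone)
        peaks = find_peaks(profile)
        assert len(peaks) == 1
        assert peaks[0][0] == int(profile.residue_ids[-1])

    def test_peaks_sorted_descending(self, clustered40):
        profile = total_coupling_averaged(clustered40)
        peaks = find_peaks(profile)
        heights = [h for _, h in peaks]
        assert heights == sorted(heights, reverse=True)
        assert peaks[0][0] == profile.hub

    def test_break_adjacent_residue_compared_to_single_neighbor(self):
        from gnmpath.coupling import CouplingProfile

        profile = CouplingProfile(
            chain_ref="x",
            residue_ids=np.array([1, 2, 3, 10, 11]),
            residue_names=("G",) * 5,
            stations=(7.0,),
            per_station_ct=np.zeros((1, 5)),
            averaged_ct=np.array([0.1, 0.5, 0.6, 0.9, 0.3]),
        )
        peaks = find_peaks(profile)
        # 3 ends its segment above its single left neighbor; 10 likewise
        assert [p for p, _ in peaks] == [10, 3]

    def test_min_height_filter(self, clustered40):
        profile = total_coupling_averaged(clustered40)
        all_peaks = find_peaks(profile, min_height_fraction=0.0)
        tall = find_peaks(profile, min_height_fraction=0.5)
        assert set(tall).issubset(set(all_peaks))
        assert all(h >= 0.5 for _, h in tall)


def test_profile_tsv_layout(clustered40):
    profile = total_coupling_averaged(clustered40)
    lines = profile_to_tsv(profile).strip().split("\n")
    assert lines[0].split("\t") == [
        "residue_number", "residue_name", "averaged_ct", "is_path_residue", "is_hub",
    ]
    assert len(lines) == clustered40.n + 1
    hub_rows = [l for l in lines[1:] if l.split("\t")[4] == "1"]
    assert len(hub_rows) == 1
    assert int(hub_rows[0].split("\t")[0]) == profile.hub
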
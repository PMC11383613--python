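"""Phantom generator: determinism, planted structure, and signal model."""

from dataclasses import replace

import numpy as np
import pytest

from striomap import (
    PhantomSpec,
    build_phantom_geometry,
    read_phantom,
    simulate_bundle,
    simulate_run,
    write_phantom,
)
from striomap.geometry import ASSOCIATION_NETWORKS, CAUDATE, LEFT, NETWORK_IDS, RIGHT
from striomap.phantom import derive_run_seed
from striomap.signal_processing import regress_nuisance

from conftest import tiny_spec


def _network_mean_series(run, labels, medial):
    """Per-network mean cortical series (nuisance-regressed proxy latents)."""
    out = {}
    for net in range(1, 16):
        sel = (labels == net) & ~medial
        out[net] = run.cortex_ts[sel].mean(axis=0)
    return out


class TestGeometry:
    def test_fixed_seed_determinism(self):
        spec = tiny_spec(rng_seed=7)
        s1, v1, t1 = build_phantom_geometry(spec)
        s2, v2, t2 = build_phantom_geometry(spec)
        assert np.array_equal(t1.vertex_labels.labels, t2.vertex_labels.labels)
        assert np.array_equal(t1.voxel_coupling, t2.voxel_coupling)
        assert np.array_equal(v1.mask, v2.mask)
        assert np.allclose(t1.voxel_baseline, t2.voxel_baseline, atol=1e-12)

    def test_association_networks_cover_caudate(self, tiny_volume, tiny_truth):
        caudate = tiny_volume.substructure_of() == CAUDATE
        present = set(np.unique(tiny_truth.voxel_coupling[caudate]))
        assert set(ASSOCIATION_NETWORKS) <= present

    def test_association_patches_in_both_hemispheres(self, tiny_surface, tiny_truth):
        labels = tiny_truth.vertex_labels.labels
        for net in ASSOCIATION_NETWORKS:
            for h in (LEFT, RIGHT):
                assert ((labels == net) & (tiny_surface.hemi == h)).sum() > 0

    def test_laterality_plan_two_to_one(self):
        spec = tiny_spec(laterality_plan={"LANG": 2.0})
        surface, _, truth = build_phantom_geometry(spec)
        lang = truth.vertex_labels.labels == NETWORK_IDS["LANG"]
        left = int((lang & (surface.hemi == LEFT)).sum())
        right = int((lang & (surface.hemi == RIGHT)).sum())
        assert abs(left - 2 * right) <= 1

    def test_somatomotor_zones_ordered_dorsolateral_to_ventromedial(
        self, tiny_volume, tiny_truth
    ):
        world = tiny_volume.world_coords()
        score = world[:, 2] + np.abs(world[:, 0])  # dorsal + lateral
        zones = tiny_truth.somatomotor_zones
        means = [score[zones[n]["voxels"]].mean() for n in ("foot", "hand", "tongue")]
        assert means[0] > means[1] > means[2]

    def test_dropout_in_ventral_striatum(self, tiny_volume, tiny_truth):
        sub = tiny_volume.substructure_of()
        assert len(tiny_truth.dropout_voxels) > 0
        assert np.all(sub[tiny_truth.dropout_voxels] > 0)
        world = tiny_volume.world_coords()
        assert world[tiny_truth.dropout_voxels, 2].mean() < world[sub > 0, 2].mean()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(frames_dropped=500, frames_per_run=422)
        with pytest.raises(ValueError):
            PhantomSpec(snr_striatum=-0.1)
        with pytest.raises(ValueError):
            PhantomSpec(laterality_plan={"NOPE": 2.0})


class TestSimulateRun:
    def test_same_seed_reproduces_bit_for_bit(self, tiny_truth):
        spec = tiny_spec()
        r1 = simulate_run(tiny_truth, spec, run_seed=123)
        r2 = simulate_run(tiny_truth, spec, run_seed=123)
        assert np.array_equal(r1.cortex_ts, r2.cortex_ts)
        assert np.array_equal(r1.striatum_ts, r2.striatum_ts)

    def test_trimming_and_nuisance_shape(self, tiny_bundle):
        run = tiny_bundle.runs[0]
        spec = tiny_bundle.spec
        assert run.n_frames == spec.frames_per_run - spec.frames_dropped
        assert run.nuisance.shape == (18, run.n_frames)
        assert np.allclose(run.nuisance.mean(axis=1), 0.0, atol=1e-10)
        # no constant rows outside dropout
        sd = run.striatum_ts.std(axis=1)
        ok = np.ones(len(sd), dtype=bool)
        ok[tiny_bundle.truth.dropout_voxels] = False
        assert np.all(sd[ok] > 0)

    def test_zero_striatal_snr_decouples(self, tiny_truth, tiny_surface):
        spec = tiny_spec(snr_striatum=0.0)
        run = regress_nuisance(simulate_run(tiny_truth, spec, run_seed=3))
        nets = _network_mean_series(run, tiny_truth.vertex_labels.labels, tiny_surface.medial_wall)
        coupled = np.flatnonzero(tiny_truth.voxel_coupling > 0)[:50]
        T = run.n_frames
        rs = []
        for v in coupled:
            ref = nets[int(tiny_truth.voxel_coupling[v])]
            rs.append(np.corrcoef(run.striatum_ts[v], ref)[0, 1])
        assert np.mean(np.abs(rs)) < 3.0 / np.sqrt(T)

    def test_coupled_voxels_prefer_own_network(self, tiny_bundle):
        truth = tiny_bundle.truth
        run = regress_nuisance(tiny_bundle.runs[0])
        nets = _network_mean_series(
            run, truth.vertex_labels.labels, tiny_bundle.surface.medial_wall
        )
        candidates = np.flatnonzero(
            (truth.voxel_coupling > 0)
            & (truth.bleed_weight < 0.05)
            & (truth.voxel_zone < 0)
        )
        candidates = candidates[~np.isin(candidates, truth.dropout_voxels)][:200]
        hits = 0
        for v in candidates:
            rs = {n: np.corrcoef(run.striatum_ts[v], s)[0, 1] for n, s in nets.items()}
            own = rs.pop(int(truth.voxel_coupling[v]))
            hits += own > max(rs.values())
        assert hits / len(candidates) >= 0.95

    def test_distinct_seeds_share_correlation_structure(self, tiny_truth):
        spec = tiny_spec()
        labels = tiny_truth.vertex_labels.labels
        coupled = np.flatnonzero(tiny_truth.voxel_coupling > 0)[:40]
        zs = []
        for seed in (11, 12):
            run = regress_nuisance(simulate_run(tiny_truth, spec, run_seed=seed))
            z = []
            for v in coupled:
                net = int(tiny_truth.voxel_coupling[v])
                sel = labels == net
                r = np.corrcoef(run.striatum_ts[v], run.cortex_ts[sel].mean(axis=0))[0, 1]
                z.append(np.arctanh(r))
            zs.append(np.asarray(z))
        diff = zs[0] - zs[1]
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 2 * se

    def test_negative_snr_rejected(self, tiny_truth):
        spec = tiny_spec()
        spec.snr_cortex = -1.0  # bypass construction-time validation
        with pytest.raises(ValueError):
            simulate_run(tiny_truth, spec, run_seed=1)

    def test_correlation_grows_with_cortical_snr(self, tiny_truth, tiny_surface):
        labels = tiny_truth.vertex_labels.labels
        medial = tiny_surface.medial_wall
        means = []
        for snr in (0.3, 1.0, 3.0):
            level = []
            for seed_offset in range(3):
                spec = tiny_spec(snr_cortex=snr)
                run = regress_nuisance(
                    simulate_run(tiny_truth, spec, run_seed=1000 + seed_offset)
                )
                # vertex vs leave-one-out mean of its own network
                rs = []
                for net in (11, 13, 15):
                    sel = np.flatnonzero((labels == net) & ~medial)[:20]
                    group = run.cortex_ts[sel]
                    for i in range(len(sel)):
                        rest = group[np.arange(len(sel)) != i].mean(axis=0)
                        rs.append(np.corrcoef(group[i], rest)[0, 1])
                level.append(np.mean(rs))
            means.append(np.mean(level))
        assert means[0] < means[1] < means[2]

    def test_no_bleed_without_bleed_fwhm(self):
        spec = tiny_spec(bleed_fwhm_mm=0.0)
        _, volume, truth = build_phantom_geometry(spec)
        assert np.all(truth.bleed_weight == 0)
        run = regress_nuisance(simulate_run(truth, spec, run_seed=9))
        labels = truth.vertex_labels.labels
        rim = truth.voxel_coupling == 0
        near = rim & (truth.surface_distance_mm <= 4.0)
        far = rim & (truth.surface_distance_mm >= 8.0)

        def adj_corr(sel):
            out = []
            for v in np.flatnonzero(sel)[:80]:
                net = labels[truth.bleed_source[v]]
                if net == 0:
                    continue
                ref = run.cortex_ts[labels == net].mean(axis=0)
                out.append(np.arctanh(np.corrcoef(run.striatum_ts[v], ref)[0, 1]))
            return np.asarray(out)

        a, b = adj_corr(near), adj_corr(far)
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert a.mean() - b.mean() < 2 * se

    def test_seed_derivation_is_stable_and_bounded(self):
        s = derive_run_seed(7, 0, 3)
        assert s == derive_run_seed(7, 0, 3)
        assert 0 <= s < 2**31
        assert s != derive_run_seed(7, 0, 4) != derive_run_seed(7, 1, 3)


class TestRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        bundle = simulate_bundle(tiny_spec(n_runs=1))
        out = tmp_path / "phantom"
        write_phantom(bundle, out)
        back = read_phantom(out)
        assert np.array_equal(
            bundle.truth.vertex_labels.labels, back.truth.vertex_labels.labels
        )
        assert np.array_equal(bundle.truth.voxel_coupling, back.truth.voxel_coupling)
        assert np.array_equal(bundle.volume.mask, back.volume.mask)
        assert np.allclose(bundle.runs[0].striatum_ts, back.runs[0].striatum_ts, rtol=0, atol=1e-6)
        assert np.allclose(bundle.runs[0].cortex_ts, back.runs[0].cortex_ts, rtol=1e-6, atol=1e-6)
        assert np.allclose(bundle.runs[0].nuisance, back.runs[0].nuisance, rtol=1e-6, atol=1e-6)

    def test_missing_directory_policy(self, tmp_path):
        bundle = simulate_bundle(tiny_spec(n_runs=1))
        with pytest.raises(FileNotFoundError):
            write_phantom(bundle, tmp_path / "nope" / "deeper", create=False)
        write_phantom(bundle, tmp_path / "made" / "deeper", create=True)
        assert (tmp_path / "made" / "deeper" / "truth_voxels.tsv").exists()
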
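"""Generator contracts: determinism, mesh invariants, field invariants and
cohort-level feature distributions."""

import numpy as np
import pytest

from dissectwall.core import REGION_TO_ID
from dissectwall.geometry_metrics import classify_growth, tortuosity
from dissectwall.synthetic_cohort import (
    DissectionParams,
    FieldConfig,
    GroupEffects,
    build_dissected_geometry,
    simulate_cohort,
    synthesize_fields,
)
from dissectwall.wall_descriptors import compute_hwd, region_summary


class TestGeometryBuild:
    def test_straight_centerline_tortuosity_one(self):
        _, cl, _ = build_dissected_geometry(DissectionParams(centerline_amplitude=0.0))
        assert tortuosity(cl) == pytest.approx(1.0)

    def test_half_flap_equal_lumen_areas(self):
        from dissectwall.geometry_metrics import section_areas

        mesh, cl, _ = build_dissected_geometry(DissectionParams(flap_angle_fraction=0.5))
        sec = section_areas(mesh, cl, 0.5 * sum(cl.markers["dissected"]))
        assert sec.tl_area == pytest.approx(sec.fl_area, rel=0.02)

    def test_determinism_byte_identical(self, default_params):
        a, _, _ = build_dissected_geometry(default_params)
        b, _, _ = build_dissected_geometry(DissectionParams(seed=7))
        assert a.vertices.tobytes() == b.vertices.tobytes()
        assert a.triangles.tobytes() == b.triangles.tobytes()
        assert a.vertex_region.tobytes() == b.vertex_region.tobytes()

    def test_oversized_tear_rejected(self):
        with pytest.raises(ValueError, match="flap extent"):
            build_dissected_geometry(DissectionParams(tear_width=40.0))
        with pytest.raises(ValueError, match="flap extent"):
            build_dissected_geometry(DissectionParams(tear_arclength=5.0))

    def test_every_vertex_labeled_once(self, geometry):
        mesh, _, _ = geometry
        assert mesh.vertex_region.shape == (mesh.n_vertices,)
        assert set(np.unique(mesh.vertex_region)) <= set(REGION_TO_ID.values())

    def test_no_overshared_edges(self, geometry):
        # watertight up to open caps and the flap seam: no edge bounds more
        # than two triangles
        mesh, _, _ = geometry
        counts = np.array(list(mesh.edge_incidence().values()))
        assert counts.max() <= 2

    def test_tear_margin_single_closed_polyline(self, geometry):
        mesh, _, _ = geometry
        margin = np.flatnonzero(mesh.vertex_region == REGION_TO_ID["tear_margin"])
        mset = set(margin.tolist())
        neigh = {v: set() for v in mset}
        for tri in mesh.triangles:
            for a, b in ((0, 1), (1, 2), (2, 0)):
                va, vb = int(tri[a]), int(tri[b])
                if va in mset and vb in mset:
                    neigh[va].add(vb)
                    neigh[vb].add(va)
        assert all(len(s) == 2 for s in neigh.values())
        # single cycle: walk it and count
        start = margin[0]
        prev, cur, steps = None, int(start), 0
        while steps <= len(margin):
            nxt = [v for v in neigh[cur] if v != prev]
            prev, cur = cur, nxt[0]
            steps += 1
            if cur == start:
                break
        assert steps == len(margin)

    def test_outlet_caps_present(self, geometry):
        mesh, _, _ = geometry
        assert {"branch1", "branch2", "branch3", "descending"} <= set(mesh.outlet_caps)
        for _, (ids, area) in mesh.outlet_caps.items():
            assert area > 0 and len(ids) > 2

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DissectionParams(flap_angle_fraction=1.2)
        with pytest.raises(ValueError):
            DissectionParams(da_radius=-1.0)


class TestFields:
    def test_mass_conservation_every_sample(self, fields, waveform, default_params):
        _, planes = fields
        total = planes.total_flux()
        q_desc = 0.55 * default_params.waveform_scale * waveform.sample(planes.times)
        # every plane, every sample: TL + FL equals the descending inflow to 1% of peak
        assert np.max(np.abs(total - q_desc[None, :])) <= 0.01 * q_desc.max()
        # and all planes carry identical total flux (exact mass conservation)
        assert np.allclose(total, total[0:1, :], rtol=1e-12)

    def test_zero_noise_zero_oscillation_gives_zero_osi(self, clean_fields):
        _, wss, _ = clean_fields
        assert np.max(compute_hwd(wss).osi) < 1e-10

    def test_fl_osi_exceeds_tl_osi(self, fields, geometry):
        mesh, _, _ = geometry
        summary = region_summary(compute_hwd(fields[0]), mesh)
        assert summary.loc["FL", "mean_osi"] > summary.loc["TL", "mean_osi"]

    def test_fl_osi_exceeds_tl_in_cohort(self, waveform, props):
        # construction mirrors the reported FL-vs-TL oscillatory-shear contrast
        wins = 0
        n = 8
        for seed in range(n):
            params = DissectionParams(seed=seed, n_theta=32, ring_spacing=6.0)
            mesh, cl, _ = build_dissected_geometry(params)
            wss, _ = synthesize_fields(mesh, waveform, props, params, centerline=cl)
            s = region_summary(compute_hwd(wss), mesh)
            wins += s.loc["FL", "mean_osi"] > s.loc["TL", "mean_osi"]
        assert wins == n

    def test_wss_tangent_to_surface(self, clean_fields):
        mesh, wss, _ = clean_fields
        normals = mesh.vertex_normals()
        dot = np.abs(np.einsum("vtk,vk->vt", wss.values, normals))
        mag = np.linalg.norm(wss.values, axis=2) + 1e-30
        # flap/junction vertices have poorly defined normals; check the bulk
        assert np.quantile(dot / mag, 0.95) < 0.2

    def test_invalid_period_rejected(self, geometry, props, default_params):
        from dissectwall.pulsatile_flow import FlowWaveform

        mesh, _, _ = geometry
        with pytest.raises(ValueError):
            FlowWaveform(np.array([0.0, 0.1]), np.array([1.0, 1.0]), -0.8)

    def test_determinism(self, geometry, waveform, props, default_params):
        mesh, cl, _ = geometry
        a, _ = synthesize_fields(mesh, waveform, props, default_params, centerline=cl)
        b, _ = synthesize_fields(mesh, waveform, props, default_params, centerline=cl)
        assert a.values.tobytes() == b.values.tobytes()


class TestCohort:
    def test_counts_and_split(self):
        recs, tables = simulate_cohort(n_per_group=11, seed=0)
        assert len(recs) == 22
        assert sum(r.group == "rapid" for r in recs) == 11
        assert len(tables) == 22

    def test_determinism(self):
        a, _ = simulate_cohort(seed=5)
        b, _ = simulate_cohort(seed=5)
        assert [r.__dict__ for r in a] == [r.__dict__ for r in b]

    def test_growth_labels_match_diameter_tables(self):
        recs, tables = simulate_cohort(seed=3)
        for r in recs:
            expected = "rapid" if r.group == "rapid" else "stable"
            assert classify_growth(tables[r.id]).label == expected

    def test_feature_ranges_within_3sd_of_reported_means(self):
        recs, _ = simulate_cohort(seed=1)
        bands = {  # (field, stable mean/sd, rapid mean/sd)
            "tl_da_ratio": ((0.42, 0.12), (0.29, 0.11)),
            "tear_area_mm2": ((144.8, 173.7), (210.0, 182.6)),
            "fl_flow_pct": ((55, 20), (63, 15)),
            "tortuosity": ((1.38, 0.29), (1.38, 0.34)),
            "initial_diameter_mm": ((35.2, 11.1), (35.5, 7.5)),
            "peak_tear_tawss_pa": ((7.9, 4.5), (10.9, 9.4)),
            "tawss_margins_pa_mm": ((255.6, 220.5), (341.8, 189.1)),
        }
        for field, (stable, rapid) in bands.items():
            for group, (m, s) in (("stable", stable), ("rapid", rapid)):
                vals = np.array([getattr(r, field) for r in recs if r.group == group])
                assert np.all(np.abs(vals.mean() - m) <= 3 * s), (field, group, vals.mean())

    def test_adverse_subgroup_direction(self):
        # emergent Table-2 direction: adverse has larger tears and higher FL flow
        tear_a, tear_f, fl_a, fl_f = [], [], [], []
        for seed in range(40):
            recs, _ = simulate_cohort(seed=seed)
            for r in recs:
                if r.subgroup == "adverse":
                    tear_a.append(r.tear_area_mm2)
                    fl_a.append(r.fl_flow_pct)
                elif r.subgroup == "favorable":
                    tear_f.append(r.tear_area_mm2)
                    fl_f.append(r.fl_flow_pct)
        assert np.mean(tear_a) > np.mean(tear_f)
        assert np.mean(fl_a) > np.mean(fl_f)

    def test_null_effects_are_exchangeable_in_mean(self):
        null = GroupEffects.null()
        vals = {"stable": [], "rapid": []}
        for seed in range(40):
            recs, _ = simulate_cohort(seed=seed, effects=null)
            for r in recs:
                vals[r.group].append(r.tl_da_ratio)
        assert np.mean(vals["stable"]) == pytest.approx(np.mean(vals["rapid"]), abs=0.02)

    def test_record_invariants(self):
        recs, _ = simulate_cohort(seed=9)
        for r in recs:
            assert 0 <= r.tl_da_ratio <= 1
            assert 0 <= r.fl_flow_pct <= 100
            assert r.tear_area_mm2 > 0 and r.tortuosity >= 1

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="negative sd"):
            GroupEffects(tl_da=(0.4, -0.1, 0.3, 0.1))

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort(n_per_group=1)
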
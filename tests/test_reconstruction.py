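"""Stacking, lofting, mesh integration and morphometry."""

import math

import numpy as np
import pytest

from sonoloft import phantom as ph
from sonoloft.geometry import Contour2D
from sonoloft.reconstruction import (
    ContourStack, MeshError, ScanProtocol, StackError, TriMesh, build_stack,
    aggregate_group, cross_section_profile, loft_mesh, mesh_volume_cog,
    relative_error_pct, structure_report, verify_phantom, write_stl,
)

from conftest import ellipse_contour, star_polygon


def circle_stack(radii, zs, n=128, label="c"):
    entries = []
    for r, z in zip(radii, zs):
        entries.append((float(z), ellipse_contour(r, r, n=n, label=label,
                                                  frame="base")))
    return ContourStack(label, entries)


class TestProtocolAndStack:
    def test_44_steps_span(self):
        p = ScanProtocol()
        assert abs(p.z_of_step(p.n_steps - 1)) == pytest.approx(215.0)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            ScanProtocol(step_mm=0)
        with pytest.raises(ValueError):
            ScanProtocol(base_view_angle_deg=90.0)

    def test_build_stack_termination(self):
        proto = ScanProtocol(step_mm=5.0, n_steps=44, view_angles_deg=(26.0,),
                             base_view_angle_deg=26.0)
        sq = Contour2D("m", [(0, 0), (10, 0), (10, 10), (0, 10)], frame="base")
        fused = {k: [sq] for k in range(10)}  # present at steps 0-9 only
        stack = build_stack("m", fused, proto)
        assert len(stack.entries) == 10

    def test_build_stack_stops_at_gap(self):
        proto = ScanProtocol(view_angles_deg=(26.0,), base_view_angle_deg=26.0)
        sq = Contour2D("m", [(0, 0), (10, 0), (10, 10), (0, 10)], frame="base")
        fused = {k: [sq] for k in list(range(5)) + list(range(8, 12))}
        stack = build_stack("m", fused, proto)
        assert len(stack.entries) == 5

    def test_too_short_stack(self):
        proto = ScanProtocol(view_angles_deg=(26.0,), base_view_angle_deg=26.0)
        sq = Contour2D("m", [(0, 0), (10, 0), (10, 10), (0, 10)], frame="base")
        with pytest.raises(StackError):
            build_stack("m", {0: [sq]}, proto)

    def test_non_uniform_z_rejected(self):
        sq = Contour2D("m", [(0, 0), (10, 0), (10, 10), (0, 10)], frame="base")
        with pytest.raises(StackError, match="non-uniform"):
            ContourStack("m", [(0.0, sq), (-5.0, sq), (-11.0, sq)])

    def test_min_csa_cutoff(self):
        proto = ScanProtocol(view_angles_deg=(26.0,), base_view_angle_deg=26.0)
        big = Contour2D("m", [(0, 0), (10, 0), (10, 10), (0, 10)], frame="base")
        tiny = Contour2D("m", [(0, 0), (0.5, 0), (0.5, 0.5), (0, 0.5)],
                         frame="base")
        fused = {0: [big], 1: [big], 2: [tiny]}
        stack = build_stack("m", fused, proto, min_csa_mm2=1.0)
        assert len(stack.entries) == 2


class TestLoftAndVolume:
    def test_prism_exact(self):
        rect = Contour2D("box", [(0, 0), (20, 0), (20, 10), (0, 10)],
                         frame="base")
        stack = ContourStack("box", [(0.0, rect), (-50.0, rect), (-100.0, rect)])
        mesh = loft_mesh(stack, n_ring=128)
        assert mesh.is_watertight()
        n_bands = 2
        assert len(mesh.faces) == 2 * 128 * n_bands + 2 * 128
        vol, cog = mesh_volume_cog(mesh)
        assert vol == pytest.approx(20000.0, rel=1e-12)
        assert cog == pytest.approx((10.0, 5.0, -50.0), abs=1e-9)

    def test_prism_volume_equals_csa_times_length_arbitrary_section(self, rng):
        pts = star_polygon(rng)
        c = Contour2D("s", pts, frame="base")
        stack = ContourStack("s", [(0.0, c), (-40.0, c)])
        vol, _ = mesh_volume_cog(loft_mesh(stack, n_ring=128))
        assert vol == pytest.approx(c.area * 40.0, rel=1e-12)

    def test_frustum_within_half_percent(self):
        zs = np.linspace(0, 100, 21)
        radii = 10 - 5 * zs / 100
        stack = circle_stack(radii, -zs)
        vol, _ = mesh_volume_cog(loft_mesh(stack))
        closed = math.pi * 100 * (100 + 50 + 25) / 3
        assert vol == pytest.approx(closed, rel=0.005)

    def test_single_slice_rejected(self):
        c = ellipse_contour(10, 10, frame="base")
        with pytest.raises(StackError):
            ContourStack("c", [(0.0, c)])

    def test_low_ring_count_rejected(self):
        stack = circle_stack([10, 10], [0, -10])
        with pytest.raises(MeshError):
            loft_mesh(stack, n_ring=8)

    def test_volume_rigid_invariance_cog_equivariance(self):
        stack = circle_stack([10, 8, 5], [0, -10, -20])
        mesh = loft_mesh(stack)
        vol, cog = mesh_volume_cog(mesh)
        shift = np.array([7.0, -3.0, 11.0])
        moved = TriMesh(mesh.vertices + shift, mesh.faces)
        vol2, cog2 = mesh_volume_cog(moved)
        assert vol2 == pytest.approx(vol, rel=1e-9)
        np.testing.assert_allclose(np.array(cog2), np.array(cog) + shift,
                                   atol=1e-6)
        # rotation about z through the origin
        t = math.radians(37.0)
        rot = np.array([[math.cos(t), -math.sin(t), 0],
                        [math.sin(t), math.cos(t), 0], [0, 0, 1.0]])
        rotated = TriMesh(mesh.vertices @ rot.T, mesh.faces)
        vol3, cog3 = mesh_volume_cog(rotated)
        assert vol3 == pytest.approx(vol, rel=1e-9)
        np.testing.assert_allclose(np.array(cog3), rot @ np.array(cog),
                                   atol=1e-6)

    def test_non_watertight_rejected(self):
        stack = circle_stack([10, 10], [0, -10])
        mesh = loft_mesh(stack)
        broken = TriMesh(mesh.vertices, mesh.faces[:-1])
        with pytest.raises(MeshError, match="watertight"):
            mesh_volume_cog(broken)

    def test_matches_trimesh_oracle(self):
        """Independent cross-check of the signed-tetrahedron integration."""
        import trimesh
        stack = circle_stack([4, 9, 12, 9, 4], [0, -5, -10, -15, -20])
        mesh = loft_mesh(stack)
        vol, cog = mesh_volume_cog(mesh)
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        assert tm.is_watertight
        assert vol == pytest.approx(tm.volume, rel=1e-9)
        np.testing.assert_allclose(np.array(cog), tm.center_mass, atol=1e-6)

    def test_stl_round_trip(self, tmp_path):
        import trimesh
        stack = circle_stack([10, 6], [0, -30])
        mesh = loft_mesh(stack)
        path = tmp_path / "m.stl"
        write_stl(mesh, path)
        back = trimesh.load(path)
        vol, _ = mesh_volume_cog(mesh)
        assert back.volume == pytest.approx(vol, rel=1e-6)


class TestMorphometry:
    def test_profile_constant_prism(self):
        rect = Contour2D("box", [(2, 1), (22, 1), (22, 11), (2, 11)],
                         frame="base")
        stack = ContourStack("box", [(0.0, rect), (-5.0, rect), (-10.0, rect)])
        prof = cross_section_profile(stack)
        assert np.allclose(prof["csa_mm2"], 200.0)
        assert np.allclose(prof["cx_mm"], 12.0)
        assert np.allclose(prof["cy_mm"], 6.0)
        assert list(prof["z_mm"]) == [0.0, -5.0, -10.0]

    def test_spindle_profile_matches_analytic(self):
        spec = ph.make_muscle_spindle()
        part = spec.parts[0]
        proto = ScanProtocol(view_angles_deg=(26.0,), base_view_angle_deg=26.0)
        fused = {k: [c.with_points(c.points, frame="base")
                     for c in ph.exact_cross_section(spec, 5.0 * k)]
                 for k in range(proto.n_steps)}
        stack = build_stack("muscle", fused, proto)
        prof = cross_section_profile(stack)
        for _, row in prof.iterrows():
            s = abs(row["z_mm"])
            analytic = math.pi * part.a(s) * part.b(s)
            assert row["csa_mm2"] == pytest.approx(analytic, rel=0.01)

    def test_group_aggregate_sums(self):
        members = [(1000.0, (0.0, 0.0, -10.0)), (3000.0, (4.0, 0.0, -30.0))]
        g = aggregate_group(members)
        assert g.volume_mm3 == 4000.0
        assert g.cog_mm == pytest.approx((3.0, 0.0, -25.0))

    def test_relative_error_definition(self):
        assert relative_error_pct(995.0, 1000.0) == pytest.approx(0.5)

    def test_structure_report_and_group(self):
        c1 = ellipse_contour(10, 10, (0, 0), label="a", frame="base")
        c2 = ellipse_contour(5, 5, (40, 0), label="b", frame="base")
        s1 = ContourStack("a", [(0.0, c1), (-10.0, c1)])
        s2 = ContourStack("b", [(0.0, c2), (-10.0, c2)])
        reports, group = structure_report([s1, s2])
        assert group.volume_mm3 == pytest.approx(
            sum(r.volume_mm3 for r in reports), rel=1e-12)

    def test_duplicate_labels_rejected(self):
        c = ellipse_contour(10, 10, label="a", frame="base")
        s = ContourStack("a", [(0.0, c), (-10.0, c)])
        with pytest.raises(ValueError, match="duplicate"):
            structure_report([s, s])

    def test_verify_phantom_flags(self):
        from sonoloft.reconstruction import StructureReport
        import pandas as pd
        prof = pd.DataFrame(columns=["z_mm", "csa_mm2", "cx_mm", "cy_mm"])
        rep = StructureReport("m", 1000.0, (0, 0, 0), prof)
        out = verify_phantom([rep], {"m": {"volume_mm3": 1000.0}})
        assert out.loc[0, "rel_err_pct"] == 0.0
        assert bool(out.loc[0, "pass"])
        rep2 = StructureReport("m", 1010.0, (0, 0, 0), prof)
        out2 = verify_phantom([rep2], {"m": {"volume_mm3": 1000.0}},
                              tolerance_pct=0.1)
        assert not bool(out2.loc[0, "pass"])

    def test_verify_missing_label(self):
        from sonoloft.reconstruction import StructureReport
        import pandas as pd
        prof = pd.DataFrame(columns=["z_mm", "csa_mm2", "cx_mm", "cy_mm"])
        rep = StructureReport("m", 1000.0, (0, 0, 0), prof)
        with pytest.raises(KeyError):
            verify_phantom([rep], {"other": {"volume_mm3": 1.0}})


class TestRefinement:
    def test_step_refinement_monotone_convergence(self):
        """Halving the step on a smooth spindle reduces the volume error;
        at 5 mm over 200 mm it is below 1%."""
        spec = ph.make_muscle_spindle()
        declared = spec.declared_volume("muscle")
        errors = []
        for step in (20.0, 10.0, 5.0):
            n = int(200.0 / step) + 1
            proto = ScanProtocol(step_mm=step, n_steps=n,
                                 view_angles_deg=(26.0,),
                                 base_view_angle_deg=26.0)
            fused = {k: [c.with_points(c.points, frame="base")
                         for c in ph.exact_cross_section(spec, step * k)]
                     for k in range(n)}
            stack = build_stack("muscle", fused, proto)
            vol, _ = mesh_volume_cog(loft_mesh(stack))
            errors.append(abs(vol - declared) / declared)
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] <= 0.01
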
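import math
from fractions import Fraction

import numpy as np
import pytest
import trimesh

from panelfish import PanelValidationError
from panelfish.topology import (
    CLUSTER_CHANNEL,
    SUBTEL_CHANNEL,
    NucleusGeometry,
    PointOutsideNucleus,
    ProbeSignal,
    call_all_pairs,
    colocalization_call,
    colocalization_table,
    distance_stats,
    envelope_distance,
    radial_profile,
    read_nuclei_table,
    read_nucleus_mesh,
    read_probes_table,
    shell_zone,
    write_nuclei_table,
    write_probes_table,
    zone_of_scale,
)

from conftest import bumpy_mesh
from oracles import (
    ellipsoid_surface_distance_oracle,
    mannwhitney_exact_p,
    mesh_surface_distance_oracle,
)


def probe(nid, channel, xyz, volume=0.15):
    return ProbeSignal(nid, channel, xyz, volume)


class TestEnvelopeDistance:
    def test_sphere_center_and_interior_points(self, sphere_nucleus):
        assert envelope_distance(sphere_nucleus, [0, 0, 0]) == (pytest.approx(5.0), False)
        assert envelope_distance(sphere_nucleus, [4, 0, 0]) == (pytest.approx(1.0), False)

    def test_outside_point_flagged_with_negative_distance(self, sphere_nucleus):
        d, outside = envelope_distance(sphere_nucleus, [6, 0, 0])
        assert outside and d == pytest.approx(-1.0)

    def test_ellipsoid_matches_dense_sampling_oracle(self, ellipsoid_nucleus, rng):
        axes = np.array([6.0, 4.0, 2.0])
        points = [np.array([5.0, 0.0, 0.0])]
        for _ in range(4):
            p = rng.uniform(-1, 1, 3)
            points.append(p / np.linalg.norm(p) * rng.uniform(0.2, 0.9)
                          * (axes * 0.9))
        for p in points:
            d, outside = envelope_distance(ellipsoid_nucleus, p)
            assert not outside
            oracle = ellipsoid_surface_distance_oracle(axes, p)
            assert d == pytest.approx(oracle, abs=1e-3)

    def test_mesh_sphere_matches_analytic(self, mesh_sphere_nucleus):
        # faceted sphere: surface within ~2e-3 of the ideal radius
        d, outside = envelope_distance(mesh_sphere_nucleus, [4.0, 0, 0])
        assert not outside
        assert d == pytest.approx(1.0, abs=5e-3)

    def test_irregular_mesh_matches_sampling_oracle(self, bumpy_nucleus, rng):
        mesh = bumpy_nucleus.mesh
        for p in ([0.0, 0.0, 0.0], [2.0, 1.0, -1.0], [-1.5, 2.0, 0.5]):
            d, outside = envelope_distance(bumpy_nucleus, p)
            assert not outside
            oracle = mesh_surface_distance_oracle(mesh, p, n_samples=200_000)
            assert d == pytest.approx(oracle, abs=1e-3)


class TestShellZone:
    def test_center_is_zone_one(self, sphere_nucleus):
        s, zone = shell_zone(sphere_nucleus, [0, 0, 0])
        assert s == 0.0 and zone == 1

    def test_envelope_is_zone_ten(self, sphere_nucleus):
        s, zone = shell_zone(sphere_nucleus, [5.0, 0, 0])
        assert s == pytest.approx(1.0) and zone == 10

    def test_half_radius_in_sphere(self):
        nuc = NucleusGeometry.from_ellipsoid("R10", [0, 0, 0], [10.0, 10.0, 10.0])
        s, zone = shell_zone(nuc, [5.0, 0, 0])
        assert s == pytest.approx(0.5)
        assert zone == 2  # ceil(10 * 0.125)

    def test_zone_boundaries_are_left_open_right_closed(self):
        # s^3 intervals ((k-1)/10, k/10]
        s_at = lambda k: (k / 10) ** (1 / 3)
        assert zone_of_scale(s_at(3)) == 3
        assert zone_of_scale(s_at(3) + 1e-9) == 4
        assert zone_of_scale(0.0) == 1

    def test_outside_point_raises_with_flag(self, sphere_nucleus):
        with pytest.raises(PointOutsideNucleus):
            shell_zone(sphere_nucleus, [7.0, 0, 0])

    def test_scaling_invariance(self, ellipsoid_nucleus):
        p = np.array([2.0, 1.0, 0.5])
        s0, z0 = shell_zone(ellipsoid_nucleus, p)
        big = NucleusGeometry.from_ellipsoid("big", [0, 0, 0],
                                             np.array([6.0, 4.0, 2.0]) * 7.5)
        s1, z1 = shell_zone(big, p * 7.5)
        assert s1 == pytest.approx(s0, abs=1e-9) and z1 == z0

    def test_mesh_bisection_matches_exact_scale_on_vertex_ray(self, mesh_sphere_nucleus):
        # a point half-way to a mesh vertex has exact scale factor 0.5
        vertex = mesh_sphere_nucleus.mesh.vertices[0]
        s = mesh_sphere_nucleus.scale_factor(0.5 * vertex)
        assert s == pytest.approx(0.5, abs=1e-5)

    def test_mesh_and_analytic_agree_on_sphere(self, mesh_sphere_nucleus, rng):
        for _ in range(10):
            u = rng.normal(size=3)
            p = u / np.linalg.norm(u) * rng.uniform(0.5, 4.5)
            s = mesh_sphere_nucleus.scale_factor(p)
            assert s == pytest.approx(np.linalg.norm(p) / 5.0, abs=5e-3)

    def test_mesh_zone_occupancy_near_uniform_for_uniform_points(self, bumpy_nucleus, rng):
        mesh = bumpy_nucleus.mesh
        lo, hi = mesh.bounds
        pts = []
        while len(pts) < 1500:
            cand = rng.uniform(lo, hi, size=(4000, 3))
            inside = bumpy_nucleus.contains(cand)
            pts.extend(cand[inside].tolist())
        pts = np.asarray(pts[:1500])
        s = bumpy_nucleus.scale_factors(pts)
        zones = zone_of_scale(s)
        frac = np.bincount(zones, minlength=11)[1:] / len(zones)
        assert np.all(np.abs(frac - 0.1) < 0.03)


class TestColocalizationCall:
    def test_overlap_mode_calls(self, sphere_nucleus):
        vol = 4 / 3 * math.pi * 0.3**3  # equivalent radius 0.3 μm
        p1 = probe("sphere", CLUSTER_CHANNEL, [0, 0, 0], vol)
        near = probe("sphere", SUBTEL_CHANNEL, [0.4, 0, 0], vol)
        far = probe("sphere", SUBTEL_CHANNEL, [0.7, 0, 0], vol)
        assert colocalization_call(p1, near, sphere_nucleus).status == "colocalized"
        assert colocalization_call(p1, far, sphere_nucleus).status == "separated"

    def test_threshold_mode_boundary_inclusive(self, sphere_nucleus):
        p1 = probe("sphere", CLUSTER_CHANNEL, [0, 0, 0], 0.001)
        p2 = probe("sphere", SUBTEL_CHANNEL, [0.5, 0, 0], 0.001)
        call = colocalization_call(p1, p2, sphere_nucleus, mode="threshold")
        assert call.status == "colocalized"

    def test_call_is_symmetric_in_probes(self, ellipsoid_nucleus, rng):
        p1 = probe("ellipsoid", CLUSTER_CHANNEL, [1.0, 0.5, 0.2])
        p2 = probe("ellipsoid", SUBTEL_CHANNEL, [2.0, -0.5, 0.1])
        a = colocalization_call(p1, p2, ellipsoid_nucleus)
        b = colocalization_call(p2, p1, ellipsoid_nucleus)
        assert a == b

    def test_probe_pair_from_different_nuclei_rejected(self, sphere_nucleus):
        p1 = probe("sphere", CLUSTER_CHANNEL, [0, 0, 0])
        p2 = probe("other", SUBTEL_CHANNEL, [1, 0, 0])
        with pytest.raises(PanelValidationError):
            colocalization_call(p1, p2, sphere_nucleus)

    def test_same_channel_rejected(self, sphere_nucleus):
        p1 = probe("sphere", CLUSTER_CHANNEL, [0, 0, 0])
        p2 = probe("sphere", CLUSTER_CHANNEL, [1, 0, 0])
        with pytest.raises(PanelValidationError):
            colocalization_call(p1, p2, sphere_nucleus)

    def test_outside_probe_flagged_excluded_from_shells_kept_in_call(self, sphere_nucleus):
        p1 = probe("sphere", CLUSTER_CHANNEL, [6.0, 0, 0])  # outside
        p2 = probe("sphere", SUBTEL_CHANNEL, [4.0, 0, 0])
        call = colocalization_call(p1, p2, sphere_nucleus)
        assert call.outside_cluster and call.zone_cluster is None
        assert call.envelope_distance_cluster == pytest.approx(-1.0)
        assert call.zone_subtel == zone_of_scale(0.8)


def _fisher_two_sided_oracle(table):
    """Exhaustive enumeration over all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    denom = math.comb(N, r1)
    probs = {}
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[aa] = Fraction(math.comb(c1, aa) * math.comb(N - c1, r1 - aa), denom)
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + Fraction(1, 10**9))))


class TestColocalizationTable:
    def _calls(self, n_coloc, n_sep):
        mk = lambda status: ProbePairCall_stub(status)
        return [mk("colocalized")] * n_coloc + [mk("separated")] * n_sep

    def test_identical_proportions_give_null_chi_square(self):
        calls = {"a": self._calls(10, 10), "b": self._calls(10, 10)}
        res = colocalization_table(calls)
        assert res.chi2_stat == pytest.approx(0.0)
        assert res.chi2_p == pytest.approx(1.0)

    def test_fisher_matches_enumeration_oracle(self):
        calls = {"ctrl": self._calls(86, 4), "case": self._calls(7, 113)}
        res = colocalization_table(calls)
        oracle = _fisher_two_sided_oracle([[86, 4], [7, 113]])
        assert res.fisher_p == pytest.approx(oracle, rel=1e-9)

    def test_empty_condition_rejected(self):
        with pytest.raises(PanelValidationError):
            colocalization_table({"a": self._calls(3, 1), "b": []})

    def test_three_conditions_have_no_fisher(self):
        calls = {c: self._calls(5, 5) for c in "abc"}
        res = colocalization_table(calls)
        assert res.fisher_p is None
        assert res.counts.shape == (3, 2)

    def test_all_colocalized_everywhere_is_trivially_null(self):
        calls = {"a": self._calls(8, 0), "b": self._calls(5, 0)}
        res = colocalization_table(calls)
        assert res.chi2_p == 1.0


class ProbePairCall_stub:
    """Minimal stand-in carrying only the fields the tables consume."""

    def __init__(self, status, zone_cluster=None, zone_subtel=None):
        self.status = status
        self.zone_cluster = zone_cluster
        self.zone_subtel = zone_subtel

    @property
    def colocalized(self):
        return self.status == "colocalized"


class TestDistanceStats:
    def test_identical_groups_give_p_one(self):
        res = distance_stats({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0]},
                             design="two_group_rank")
        assert res.p_value == 1.0

    def test_fully_separated_small_groups(self):
        res = distance_stats({"a": [1, 2, 3], "b": [10, 11, 12]},
                             design="two_group_rank")
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(mannwhitney_exact_p([1, 2, 3], [10, 11, 12]))

    def test_exact_p_matches_enumeration_on_random_groups(self, rng):
        for m, n in [(3, 4), (5, 5), (2, 5), (4, 4)]:
            x = rng.normal(size=m)
            y = rng.normal(size=n)
            res = distance_stats({"a": x, "b": y}, design="two_group_rank")
            assert res.p_value == pytest.approx(mannwhitney_exact_p(x, y), rel=1e-9)

    def test_three_identical_groups_kruskal_null(self):
        res = distance_stats({c: [2.0, 2.0, 2.0] for c in "abc"},
                             design="multi_group_rank")
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_anova_on_shifted_groups(self, rng):
        groups = {"a": rng.normal(0, 1, 20), "b": rng.normal(3, 1, 20)}
        res = distance_stats(groups, design="multi_group_anova")
        assert res.p_value < 1e-6
        assert set(res.descriptives.columns) == {"n", "mean", "sem"}

    def test_empty_group_rejected(self):
        with pytest.raises(PanelValidationError):
            distance_stats({"a": [1.0], "b": []})

    def test_descriptives_mean_sem(self):
        res = distance_stats({"a": [1.0, 2.0, 3.0], "b": [5.0, 7.0]},
                             design="two_group_rank")
        assert res.descriptives.loc["a", "mean"] == pytest.approx(2.0)
        assert res.descriptives.loc["a", "sem"] == pytest.approx(
            np.std([1, 2, 3], ddof=1) / math.sqrt(3))


class TestRadialProfile:
    def test_envelope_probes_concentrate_in_zone_ten(self):
        calls = [ProbePairCall_stub("separated", zone_cluster=10, zone_subtel=10)
                 for _ in range(5)]
        prof = radial_profile({"cond": calls, "cond2": calls})
        assert prof.occupancy.loc[("cond", CLUSTER_CHANNEL), 10] == 1.0

    def test_planted_interior_vs_peripheral_distributions_differ(self, rng):
        def calls_at(s):
            zone = zone_of_scale(s)
            return [ProbePairCall_stub("separated", zone_cluster=zone,
                                       zone_subtel=zone) for _ in range(60)]
        prof = radial_profile({"peripheral": calls_at(0.99),
                               "interior": calls_at(0.5)})
        stat, p = prof.chi2_by_channel[CLUSTER_CHANNEL]
        assert p < 0.05


class TestGeometryIO:
    def test_nuclei_table_round_trip(self, tmp_path):
        nuclei = {
            "n1": NucleusGeometry.from_ellipsoid("n1", [1, 2, 3], [6, 4, 2]),
            "n2": NucleusGeometry.from_ellipsoid("n2", [0, 0, 0], [5, 5, 5]),
        }
        p = tmp_path / "nuclei.tsv"
        write_nuclei_table(nuclei, p)
        back = read_nuclei_table(p)
        assert set(back) == {"n1", "n2"}
        np.testing.assert_allclose(back["n1"].ellipsoid[1], [6, 4, 2])

    def test_probes_table_round_trip(self, tmp_path):
        probes = [probe("n1", CLUSTER_CHANNEL, [1.5, 2.5, 3.5], 0.2),
                  probe("n1", SUBTEL_CHANNEL, [1.0, 2.0, 3.0], 0.1)]
        p = tmp_path / "probes.tsv"
        write_probes_table(probes, p)
        back = read_probes_table(p)
        assert back[0].channel == CLUSTER_CHANNEL
        np.testing.assert_allclose(back[1].gravity_center, [1.0, 2.0, 3.0])

    def test_ply_mesh_load_requires_watertight(self, tmp_path):
        mesh = bumpy_mesh(subdivisions=2)
        p = tmp_path / "nuc.ply"
        mesh.export(p, encoding="ascii")
        nuc = read_nucleus_mesh(p)
        assert nuc.mesh.is_watertight
        holey = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces[:-5],
                                process=False)
        p2 = tmp_path / "holey.ply"
        holey.export(p2, encoding="ascii")
        with pytest.raises(PanelValidationError, match="watertight"):
            read_nucleus_mesh(p2)

    def test_call_all_pairs_requires_two_channel_pairs(self, sphere_nucleus):
        probes = [probe("sphere", CLUSTER_CHANNEL, [0, 0, 0])]
        with pytest.raises(PanelValidationError, match="two-channel"):
            call_all_pairs({"sphere": sphere_nucleus}, probes)

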
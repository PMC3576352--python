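import numpy as np
import pytest

from petquant import (EncoderConfig, GraphConfig, PetVolume, detect_iurs,
                      dice, segment_iur)
from petquant.iur_detection import IUR, SeedSet
from petquant.kde import KdeDensity
from petquant.random_walker import (WeightedGraph, build_graph,
                                    solve_dirichlet, WEIGHT_EPS)

WEIGHT_EPS_TOL = 2e-6


def full_region(vol: PetVolume) -> IUR:
    idx = np.argwhere(np.ones(vol.shape, bool))
    return IUR(voxel_ids=idx, suv_max=float(vol.values.max()),
               bbox=tuple((0, s - 1) for s in vol.shape))


def dense_oracle(graph: WeightedGraph, seeds: SeedSet) -> np.ndarray:
    """Independent dense solve of the Dirichlet system (gamma = 0)."""
    n = graph.n_vertices
    W = np.zeros((n, n))
    for (i, j), w in zip(graph.edges, graph.weights):
        W[i, j] += w
        W[j, i] += w
    L = np.diag(W.sum(axis=1)) - W
    lo = np.array([s.start for s in graph.crop])
    fg = np.ravel_multi_index(tuple((np.atleast_2d(seeds.foreground) - lo).T),
                              graph.shape)
    bg = np.ravel_multi_index(tuple((np.atleast_2d(seeds.background) - lo).T),
                              graph.shape)
    x = np.zeros(n)
    x[fg] = 1.0
    labeled = np.zeros(n, bool)
    labeled[fg] = labeled[bg] = True
    u = ~labeled
    x[u] = np.linalg.solve(L[np.ix_(u, u)], -L[np.ix_(u, labeled)] @ x[labeled])
    return x


def path_graph(n=5):
    g = WeightedGraph(crop=(slice(0, n), slice(0, 1), slice(0, 1)),
                      shape=(n, 1, 1),
                      edges=np.array([[i, i + 1] for i in range(n - 1)]),
                      weights=np.ones(n - 1), suv=np.zeros(n))
    seeds = SeedSet(foreground=np.array([[0, 0, 0]]),
                    background=np.array([[n - 1, 0, 0]]))
    return g, seeds


class TestDirichletSolve:
    def test_path_graph_is_linear(self):
        g, seeds = path_graph(5)
        field = solve_dirichlet(g, seeds)
        np.testing.assert_allclose(field.values.ravel(),
                                   [1.0, 0.75, 0.5, 0.25, 0.0], atol=1e-10)

    def test_path_midpoint_half_by_symmetry(self):
        g, seeds = path_graph(5)
        assert solve_dirichlet(g, seeds).values[2, 0, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("shape", [(4, 4, 1), (6, 6, 1), (8, 8, 1),
                                       (5, 3, 2), (4, 4, 3)])
    @pytest.mark.parametrize("trial", range(3))
    def test_matches_dense_oracle_on_random_lattices(self, shape, trial, rng):
        vol = PetVolume(rng.uniform(0, 10, shape))
        region = full_region(vol)
        all_idx = region.voxel_ids
        picks = rng.choice(len(all_idx), size=4, replace=False)
        seeds = SeedSet(foreground=all_idx[picks[:2]],
                        background=all_idx[picks[2:]])
        graph = build_graph(vol, region, seeds,
                            GraphConfig(crop_margin=0, beta=50))
        field = solve_dirichlet(graph, seeds)
        expected = dense_oracle(graph, seeds)
        np.testing.assert_allclose(field.values.ravel(), expected, atol=1e-8)

    def test_harmonic_at_every_unlabeled_vertex(self, rng):
        vol = PetVolume(rng.uniform(0, 10, (6, 6, 2)))
        region = full_region(vol)
        idx = region.voxel_ids
        picks = rng.choice(len(idx), size=6, replace=False)
        seeds = SeedSet(foreground=idx[picks[:3]], background=idx[picks[3:]])
        graph = build_graph(vol, region, seeds, GraphConfig(crop_margin=0))
        x = solve_dirichlet(graph, seeds).values.ravel()
        labeled = set()
        lo = np.array([s.start for s in graph.crop])
        for pts in (seeds.foreground, seeds.background):
            for p in np.atleast_2d(pts):
                labeled.add(np.ravel_multi_index(tuple(p - lo), graph.shape))
        nbr_num = np.zeros(graph.n_vertices)
        nbr_den = np.zeros(graph.n_vertices)
        for (i, j), w in zip(graph.edges, graph.weights):
            nbr_num[i] += w * x[j]
            nbr_num[j] += w * x[i]
            nbr_den[i] += w
            nbr_den[j] += w
        for v in range(graph.n_vertices):
            if v not in labeled:
                assert x[v] == pytest.approx(nbr_num[v] / nbr_den[v], abs=1e-8)

    def test_maximum_principle(self, rng):
        vol = PetVolume(rng.uniform(0, 5, (7, 7, 1)))
        region = full_region(vol)
        idx = region.voxel_ids
        picks = rng.choice(len(idx), size=4, replace=False)
        seeds = SeedSet(foreground=idx[picks[:2]], background=idx[picks[2:]])
        graph = build_graph(vol, region, seeds, GraphConfig(crop_margin=0))
        x = solve_dirichlet(graph, seeds).values
        assert x.min() >= -1e-9 and x.max() <= 1 + 1e-9

    def test_gamma_pulls_toward_prior_ratio(self):
        g, seeds = path_graph(7)
        grid = np.linspace(-1, 2, 64)
        bump = np.exp(-0.5 * ((grid - 0.0) / 0.2) ** 2)
        bump /= np.trapezoid(bump, grid)
        flat = np.ones_like(grid) / np.trapezoid(np.ones_like(grid), grid)
        priors = (KdeDensity(grid, bump, 0.2), KdeDensity(grid, flat, 1.0))
        # all suv = 0 -> lam_fg is the same at every vertex
        ratio = bump[np.argmin(np.abs(grid))] / (
            bump[np.argmin(np.abs(grid))] + flat[0])
        prev_dist = np.abs(
            solve_dirichlet(g, seeds, priors=priors, gamma=0.01).values.ravel()[1:-1]
            - ratio).mean()
        for gamma in (0.1, 1.0, 10.0, 100.0, 1000.0):
            x = solve_dirichlet(g, seeds, priors=priors, gamma=gamma).values.ravel()
            dist = np.abs(x[1:-1] - ratio).mean()
            # stronger priors pull the field toward the prior ratio
            assert dist <= prev_dist + 1e-12
            prev_dist = dist
        assert prev_dist < 0.01  # asymptotically the prior dominates


class TestBuildGraph:
    def test_equal_suv_edge_weight_is_one(self):
        vol = PetVolume(np.full((2, 1, 1), 3.0))
        region = full_region(vol)
        seeds = SeedSet(foreground=np.array([[0, 0, 0]]),
                        background=np.array([[1, 0, 0]]))
        graph = build_graph(vol, region, seeds, GraphConfig(crop_margin=0))
        assert graph.weights[0] == pytest.approx(1.0, abs=WEIGHT_EPS_TOL)

    def test_extreme_contrast_weight(self):
        vol = PetVolume(np.array([[[0.0]], [[10.0]]]))
        region = full_region(vol)
        seeds = SeedSet(foreground=np.array([[1, 0, 0]]),
                        background=np.array([[0, 0, 0]]))
        graph = build_graph(vol, region, seeds,
                            GraphConfig(beta=90, crop_margin=0))
        assert graph.weights[0] == pytest.approx(np.exp(-90) + WEIGHT_EPS)

    def test_inplane_lattice_edge_count(self):
        # 3x3 single-slice crop, 6-connectivity -> 2 * 2*3 = 12 edges
        vol = PetVolume(np.ones((3, 3, 1)))
        region = full_region(vol)
        seeds = SeedSet(foreground=np.array([[0, 0, 0]]),
                        background=np.array([[2, 2, 0]]))
        graph = build_graph(vol, region, seeds, GraphConfig(crop_margin=0))
        assert len(graph.edges) == 12

    @pytest.mark.parametrize("connectivity,n_edges", [(6, 144), (18, 360),
                                                      (26, 468)])
    def test_3d_connectivity_edge_counts(self, connectivity, n_edges):
        # 4x4x4 lattice: 3 face offsets x 48 pairs; +6 diagonal offsets x 36;
        # +4 corner offsets x 27
        vol = PetVolume(np.ones((4, 4, 4)))
        region = full_region(vol)
        seeds = SeedSet(foreground=np.array([[0, 0, 0]]),
                        background=np.array([[3, 3, 3]]))
        graph = build_graph(vol, region, seeds,
                            GraphConfig(connectivity=connectivity,
                                        crop_margin=0))
        assert len(graph.edges) == n_edges


class TestSegmentIur:
    def test_noiseless_cube_recovered_exactly(self):
        vals = np.ones((9, 9, 9))
        vals[3:6, 3:6, 3:6] = 8.0
        vol = PetVolume(vals)
        region = detect_iurs(vol, EncoderConfig(lower=0.4))[0]
        mask = segment_iur(vol, region)
        truth = vals == 8.0
        assert dice(mask, truth) == 1.0

    def test_foreground_seeds_inside_mask_background_outside(self):
        vals = np.ones((9, 9, 9))
        vals[3:6, 3:6, 3:6] = 8.0
        vals[4, 4, 4] = 9.0
        vol = PetVolume(vals)
        region = detect_iurs(vol, EncoderConfig(lower=0.4))[0]
        from petquant.iur_detection import place_seeds

        seeds = place_seeds(vol, region, fg_quantile=0.5)
        mask = segment_iur(vol, region)
        for p in np.atleast_2d(seeds.foreground):
            assert mask[tuple(p)]
        for p in np.atleast_2d(seeds.background):
            assert not mask[tuple(p)]

    def test_noisy_sphere_accuracy(self):
        import petquant as pq

        spec = pq.PhantomSpec(
            lesions=(pq.LesionSpec(shape="sphere", center_mm=(192, 192, 88),
                                   radius_mm=20.0, peak_suv=8.0,
                                   texture_seed=7),),
            noise_sd=0.5, seed=7)
        vol, truths = pq.generate_phantom(spec)
        res = pq.segment_volume(vol, pq.PipelineConfig(compute_features=False))
        matched = pq.match_to_truth(res, truths)
        assert matched[0] is not None
        assert dice(matched[0], truths[0]) >= 0.85
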
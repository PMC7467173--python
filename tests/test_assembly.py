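"""Assembly scoring terms, MC-SA sampling against exhaustive
enumeration, convergence assessment and the iterative loop."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import domfit as df
from domfit import assembly as asm
from domfit.assembly import (
    NOT_FOUND,
    CrossLink,
    assess_convergence,
    centroid_energy,
    clash_score,
    crosslink_penalty,
    iterative_assemble,
    mcsa_sample,
    proximity_score,
    slide_into_contact,
    split_subdomains,
    trim_clashing_residues,
)
from domfit.config import AnnealSchedule, RunConfig
from domfit.docking import ca_rmsd_between_placements
from domfit.errors import NoAxisError
from domfit.fixtures import (
    make_crosslinks,
    make_decoys,
    make_helix_bundle_domain,
    make_toy_complex,
)
from domfit.structure import Placement, apply_placement, assign_secondary_structure

from conftest import ca_domain, random_blob_domain


def translate(domain, vec):
    return apply_placement(domain, Placement(np.eye(3), np.asarray(vec, float)))


@pytest.fixture(scope="module")
def toy_problem():
    """3 domains x 4 candidates with clean cross-links, reused read-only."""
    toy = make_toy_complex(3, 50, seed=3)
    density = toy.simulated_map(10.0)
    cands, truth_idx = make_decoys(toy, 3, seed=103)
    links = make_crosslinks(toy, 8, 0.0, seed=203)
    problem = asm.AssemblyProblem(toy.domains, cands, density, links,
                                  RunConfig(), 10.0)
    truth = np.array([truth_idx[s.name] for s in problem.slots])
    return problem, truth


class TestSlideIntoContact:
    def test_already_in_contact_stays_put(self):
        a = random_blob_domain(15, seed=0)
        b = translate(random_blob_domain(15, seed=1), [14.0, 0.0, 0.0])
        # ensure contact without clash at start, else skip construction
        a2, b2, ok = slide_into_contact(a, b)
        if ok:
            # displacement only when the start violates the condition
            start_ok = True
            from scipy.spatial import cKDTree

            dmin = cKDTree(a.ca_coords).query(b.ca_coords)[0].min()
            if 4.0 <= dmin < 8.0:
                assert np.allclose(a2.coords, a.coords)
                assert np.allclose(b2.coords, b.coords)

    def test_clashing_spheres_separate_within_limit(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(30, 3)) * 3.0
        a = ca_domain(pts, label="a")
        b = ca_domain(pts + [2.0, 0.0, 0.0], label="b", res_start=100)
        a2, b2, ok = slide_into_contact(a, b, max_shift=5.0)
        from scipy.spatial import cKDTree

        if ok:
            dmin = cKDTree(a2.ca_coords).query(b2.ca_coords)[0].min()
            assert dmin >= 4.0
        disp = np.linalg.norm(a2.centroid - a.centroid) + np.linalg.norm(
            b2.centroid - b.centroid
        )
        assert disp <= 5.0 + 1e-6

    def test_displacement_never_exceeds_limit(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = ca_domain(rng.normal(size=(20, 3)) * 4, label="a")
            b = ca_domain(rng.normal(size=(20, 3)) * 4 + [10, 0, 0], label="b",
                          res_start=50)
            a2, b2, _ = slide_into_contact(a, b, max_shift=5.0)
            disp = np.linalg.norm(a2.centroid - a.centroid) + np.linalg.norm(
                b2.centroid - b.centroid
            )
            assert disp <= 5.0 + 1e-6

    def test_coincident_centroids_raise(self):
        a = random_blob_domain(10, seed=2)
        with pytest.raises(NoAxisError):
            slide_into_contact(a, a.copy())


class TestClashScore:
    def test_far_apart_is_zero(self):
        a = random_blob_domain(20, seed=0)
        assert clash_score(a, translate(a, [50.0, 0, 0])) == 0.0

    def test_superposed_domains_exceed_severe_threshold(self):
        cfg = RunConfig()
        a = random_blob_domain(10, seed=1)
        assert clash_score(a, a.copy()) > cfg.severe_clash_threshold

    def test_monotone_along_separation_axis(self):
        # two tight clusters pulled apart beyond their internal spread:
        # every pair distance grows, so the soft-sphere sum cannot rise
        a = random_blob_domain(15, seed=3, scale=0.8)
        scores = [
            clash_score(a, translate(a, [d, 0.0, 0.0]))
            for d in np.linspace(3.0, 12.0, 19)
        ]
        assert scores[0] > 0
        assert all(s1 >= s2 - 1e-9 for s1, s2 in zip(scores, scores[1:]))
        assert scores[-1] == 0.0


class TestTrimClashingResidues:
    def _helix(self, label="h", res_start=1):
        return make_helix_bundle_domain(
            40, label=label, res_start=res_start, n_helices=2, with_cb=False
        )

    def test_clash_free_pair_unchanged(self):
        a, b = self._helix("a"), translate(self._helix("b", 100), [40.0, 0, 0])
        sse_a, sse_b = (assign_secondary_structure(d) for d in (a, b))
        a2, b2 = trim_clashing_residues(a, b, sse_a, sse_b)
        assert a2 is a and b2 is b

    def test_clash_from_secondary_structure_trims_nothing(self):
        # severely clashing pair whose residues are all helical:
        # condition (i) (no secondary structure) blocks every removal
        a = self._helix("a")
        b = translate(self._helix("b", 100), [1.0, 0.5, 0.0])
        sse_a = np.full(a.n_residues, "H")
        sse_b = np.full(b.n_residues, "H")
        assert clash_score(a, b) > RunConfig().severe_clash_threshold
        a2, b2 = trim_clashing_residues(a, b, sse_a, sse_b)
        assert a2.n_residues == a.n_residues
        assert b2.n_residues == b.n_residues

    def test_exposed_loop_clash_is_trimmed(self):
        cfg = RunConfig()
        # domain a: compact core plus a protruding 3-residue loop buried
        # inside domain b's core
        rng = np.random.default_rng(4)
        core = rng.normal(size=(25, 3)) * 3.0
        loop = np.array([[20.0, 0.0, 0.0], [20.0, 2.0, 0.0], [20.0, -2.0, 0.0]])
        a = ca_domain(np.vstack([core, loop]), label="a")
        b = ca_domain(rng.normal(size=(25, 3)) * 1.8 + [20.0, 0.0, 0.0],
                      label="b", res_start=100)
        sse_a = np.array(["L"] * 28)
        sse_b = np.array(["L"] * 25)
        before = clash_score(a, b, cfg.clash_dist)
        assert before > cfg.severe_clash_threshold
        a2, b2 = trim_clashing_residues(a, b, sse_a, sse_b, cfg)
        assert 26 not in a2.residue_ids           # the protruding residues
        after = clash_score(a2, b2, cfg.clash_dist)
        assert after < before


class TestSplitSubdomains:
    def test_single_globule_stays_whole(self):
        dom = make_helix_bundle_domain(80, rng=np.random.default_rng(1))
        assert len(split_subdomains(dom)) == 1

    def test_two_globules_with_linker_split_in_linker(self):
        g1 = make_helix_bundle_domain(
            60, with_cb=False, rng=np.random.default_rng(2)
        ).ca_coords
        # 20-residue extended linker (3.8 Å per residue), then a second
        # displaced globule
        linker = np.stack(
            [np.arange(1, 21) * 3.8, np.zeros(20), np.zeros(20)], axis=1
        ) + g1[-1]
        g2 = make_helix_bundle_domain(
            60, with_cb=False, rng=np.random.default_rng(3)
        ).ca_coords + linker[-1] + [15.0, 0, 0]
        dom = ca_domain(np.vstack([g1, linker, g2]), label="two")
        parts = split_subdomains(dom)
        assert len(parts) == 2
        cut = parts[0].res_end + 1
        assert 61 - 5 <= cut <= 80 + 5   # inside the linker +- 5 residues

    def test_segments_partition_residues(self):
        g1 = make_helix_bundle_domain(
            50, with_cb=False, rng=np.random.default_rng(4)
        ).ca_coords
        linker = np.stack(
            [np.linspace(0, 40, 15), np.zeros(15), np.zeros(15)], axis=1
        ) + g1[-1] + [3.0, 0, 0]
        g2 = make_helix_bundle_domain(
            50, with_cb=False, rng=np.random.default_rng(5)
        ).ca_coords + linker[-1] + [12.0, 0, 0]
        dom = ca_domain(np.vstack([g1, linker, g2]), label="two")
        parts = split_subdomains(dom)
        all_res = sorted(r for p in parts for r in p.residue_ids)
        assert all_res == sorted(dom.residue_ids)


class TestCentroidEnergy:
    def test_far_pair_is_zero(self):
        a = random_blob_domain(20, seed=0)
        assert centroid_energy(a, translate(a, [120.0, 0, 0])) == 0.0

    def test_contact_interface_is_negative(self):
        # two flat sheets of beads 6 Å apart: every pair in the well
        xs, ys = np.meshgrid(np.arange(6) * 6.0, np.arange(5) * 6.0)
        sheet = np.stack([xs.ravel(), ys.ravel(), np.zeros(30)], axis=1)
        a = ca_domain(sheet, label="a")
        b = ca_domain(sheet + [0, 0, 6.0], label="b", res_start=100)
        e = centroid_energy(a, b)
        assert e < 0

    def test_superposed_pair_strongly_positive(self):
        a = random_blob_domain(15, seed=6, scale=3.0)
        assert centroid_energy(a, a.copy()) > 10.0


class TestProximityScore:
    def _pair(self, gap_vec, n_link=10):
        a = ca_domain(np.stack([np.arange(10) * 3.8, np.zeros(10),
                                np.zeros(10)], 1), label="a", res_start=1)
        b_coords = np.stack([np.arange(10) * 3.8, np.zeros(10), np.zeros(10)], 1)
        b_coords += np.asarray(gap_vec) + a.ca_coords[-1]
        b = ca_domain(b_coords, label="b", res_start=10 + n_link + 1)
        a.n_link_next = n_link
        b.n_link_prev = n_link
        return a, b

    def test_closable_gap_is_free(self):
        a, b = self._pair([10.0, 0, 0], n_link=10)
        assert proximity_score(a, b) == 0.0   # 10 <= 10*3.5 + 4

    def test_different_chains_zero(self):
        a, _ = self._pair([100.0, 0, 0])
        b = ca_domain(np.random.default_rng(0).normal(size=(10, 3)) + 500,
                      label="b", chain="B", res_start=50)
        assert proximity_score(a, b) == 0.0

    def test_monotone_in_gap(self):
        gaps = np.linspace(30, 80, 11)
        pens = [proximity_score(*self._pair([g, 0, 0], n_link=10)) for g in gaps]
        assert all(p2 >= p1 - 1e-9 for p1, p2 in zip(pens, pens[1:]))
        assert pens[-1] > 0

    def test_non_adjacent_same_chain_zero(self):
        a, b = self._pair([100.0, 0, 0], n_link=10)
        b.res_start += 37   # numbering gap no longer matches the linker
        b.res_end += 37
        assert proximity_score(a, b) == 0.0


class TestCrosslinkPenalty:
    def test_flat_bottom_and_linear_beyond(self):
        assert crosslink_penalty(12.0, threshold=30.0) == 0.0
        assert crosslink_penalty(40.0, threshold=30.0, slope=1.0) == 10.0
        assert crosslink_penalty(500.0, threshold=30.0, cap=30.0) == 30.0

    def test_invalid_link_rejected(self):
        with pytest.raises(ValueError):
            CrossLink("A", 5, "A", 5)
        with pytest.raises(ValueError):
            CrossLink("A", 1, "A", 2, threshold=-1.0)


class TestTotalScore:
    def test_all_not_found_is_offset_sum(self, toy_problem):
        problem, _ = toy_problem
        n = len(problem.slots)
        state = problem.state(np.full(n, NOT_FOUND))
        expected = n * problem.cfg.not_found_offset
        assert state.total_score == pytest.approx(expected)
        assert state.breakdown["n_not_found"] == n

    def test_breakdown_weighted_sum_matches_total(self, toy_problem):
        problem, truth = toy_problem
        w = problem.cfg.weights
        for assignment in ([0, 1, 2], truth, [NOT_FOUND, 0, 1]):
            st = problem.state(np.array(assignment))
            recomposed = (
                w.w_dens * st.breakdown["dens"]
                + w.w_centroid_energy * st.breakdown["centroid_energy"]
                + w.w_proximity * st.breakdown["proximity"]
                + w.w_distance_constraint * st.breakdown["distance_constraint"]
                + st.breakdown["n_not_found"] * problem.cfg.not_found_offset
            )
            assert recomposed == pytest.approx(st.total_score, abs=1e-6)

    def test_table_score_equals_explicit_state_score(self, toy_problem):
        problem, _ = toy_problem
        for st in problem.enumerate_states():
            assert problem.score(st.assignment) == pytest.approx(
                st.total_score, abs=1e-6
            )

    def test_pair_cache_symmetry(self, toy_problem):
        problem, _ = toy_problem
        for (i, p, j, q), entry in problem.pair_cache.items():
            assert problem.pair_entry(j, q, i, p) is entry

    def test_truth_is_enumeration_optimum(self, toy_problem):
        problem, truth = toy_problem
        best = problem.enumerate_states()[0]
        assert np.array_equal(best.assignment, truth)


class TestMCSA:
    def test_finds_enumerated_optimum(self, toy_problem):
        problem, _ = toy_problem
        best = problem.enumerate_states()[0]
        sched = AnnealSchedule(n_steps=5000, kT_start=100, kT_end=1,
                               n_trajectories=200, seed=42)
        tops = mcsa_sample(problem, sched)
        assert np.array_equal(tops[0].assignment, best.assignment)
        assert tops[0].total_score == pytest.approx(best.total_score)

    def test_zero_temperature_is_greedy_descent(self, toy_problem):
        problem, _ = toy_problem
        sched = AnnealSchedule(n_steps=2000, kT_start=1e-9, kT_end=1e-9,
                               n_trajectories=50, seed=7)
        tops = mcsa_sample(problem, sched)
        # greedy descent still reaches locally minimal states; scores
        # must not exceed the random-start expectation by construction:
        # every accepted move lowered the score
        assert tops[0].total_score <= problem.state(
            np.full(len(problem.slots), NOT_FOUND)
        ).total_score + 1e-9

    def test_same_seed_reproduces_top10(self, toy_problem):
        problem, _ = toy_problem
        sched = AnnealSchedule(n_steps=3000, kT_start=100, kT_end=1,
                               n_trajectories=100, seed=9)
        tops1 = mcsa_sample(problem, sched)
        tops2 = mcsa_sample(problem, sched)
        assert len(tops1) == len(tops2)
        for s1, s2 in zip(tops1, tops2):
            assert np.array_equal(s1.assignment, s2.assignment)
            assert s1.total_score == s2.total_score
            assert s1.multiplicity == s2.multiplicity


class TestAssessConvergence:
    def test_identical_states_freeze_everything(self, toy_problem):
        problem, truth = toy_problem
        st = problem.state(truth)
        st.multiplicity = 1
        frozen = assess_convergence(problem, [st] * 10)
        assert set(frozen) == set(range(len(problem.slots)))
        for si, k in frozen.items():
            assert k == truth[si]

    def test_majority_six_of_ten_freezes(self, toy_problem):
        problem, truth = toy_problem
        other = truth.copy()
        other[0] = (truth[0] + 1) % problem.n_options[0]
        states = [problem.state(truth) for _ in range(6)] + [
            problem.state(other) for _ in range(4)
        ]
        frozen = assess_convergence(problem, states)
        assert frozen.get(0) == truth[0]

    def test_five_five_split_does_not_freeze(self, toy_problem):
        problem, truth = toy_problem
        other = truth.copy()
        other[0] = (truth[0] + 1) % problem.n_options[0]
        states = [problem.state(truth) for _ in range(5)] + [
            problem.state(other) for _ in range(5)
        ]
        frozen = assess_convergence(problem, states)
        assert 0 not in frozen


class TestIterativeAssemble:
    @pytest.fixture(scope="class")
    def toy4(self):
        toy = make_toy_complex(4, 50, seed=7)
        density = toy.simulated_map(10.0)
        cands, truth_idx = make_decoys(toy, 3, seed=107)
        links = make_crosslinks(toy, 5, 0.0, seed=207)
        return toy, density, cands, links

    def _desk_config(self, seed=11):
        cfg = RunConfig()
        cfg.schedule = AnnealSchedule(n_steps=5000, kT_start=100.0, kT_end=1.0,
                                      n_trajectories=200, seed=seed)
        return cfg

    def test_converged_round_one_terminates_round_two(self, toy4):
        toy, density, cands, links = toy4
        state, problem, log = iterative_assemble(
            toy.domains, density, links, self._desk_config(), 10.0,
            candidates=dict(cands), max_rounds=5,
        )
        assert len(log) == 2
        assert log[1]["newly_frozen"] == {}

    def test_recovers_planted_complex(self, toy4):
        toy, density, cands, links = toy4
        state, problem, log = iterative_assemble(
            toy.domains, density, links, self._desk_config(), 10.0,
            candidates=dict(cands), max_rounds=5,
        )
        for si, slot in enumerate(problem.slots):
            k = int(state.assignment[si])
            assert k != NOT_FOUND
            dom = slot.variants[slot.options[k].variant]
            rms = ca_rmsd_between_placements(
                dom, slot.options[k].placement, toy.true_placements[dom.label]
            )
            assert rms < 3.0

    def test_frozen_set_never_shrinks(self, toy4):
        toy, density, cands, links = toy4
        _, _, log = iterative_assemble(
            toy.domains, density, links, self._desk_config(), 10.0,
            candidates=dict(cands), max_rounds=5,
        )
        counts = [entry["n_frozen_before"] for entry in log]
        assert counts == sorted(counts)

    def test_always_clashing_domain_ends_not_found(self):
        toy = make_toy_complex(2, 50, seed=9)
        density = toy.simulated_map(10.0)
        cands, _ = make_decoys(toy, 1, seed=109)
        # give the second domain only candidates superposed on the first
        pl0 = toy.true_placements["D0"]
        d1 = toy.domains[1]
        bad = Placement(
            np.eye(3),
            pl0.apply(toy.domains[0].coords, toy.domains[0].centroid).mean(0)
            - d1.centroid,
        )
        cands["D1"] = [bad]
        cfg = self._desk_config()
        problem = asm.AssemblyProblem(toy.domains, cands, density, None, cfg, 10.0)
        best = problem.enumerate_states()[0]
        d1_slot = [i for i, s in enumerate(problem.slots) if s.name == "D1"][0]
        assert best.assignment[d1_slot] == NOT_FOUND
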
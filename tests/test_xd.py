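import math

import numpy as np
import pytest

from walkset.io import GeneSet, Network, TissueAnnotation, map_set
from walkset.rwr import DistanceVector
from walkset.xd import (
    BinScheme,
    PathwayProfile,
    build_bin_scheme,
    compare_tissue_groups,
    profile_pathway,
    profile_scores,
    score_collection,
    xd_score,
)

H = lambda n: sum(1.0 / i for i in range(1, n + 1))  # harmonic numbers


def uniform_scheme(n_bins: int = 10) -> BinScheme:
    """Scheme over [0, 1) with an exactly uniform background."""
    pooled = np.arange(1000) / 1000.0
    scheme = build_bin_scheme(pooled, n_bins=n_bins)
    assert np.allclose(scheme.background_fractions, 1 / n_bins)
    return scheme


def make_profile(fractions, n_scores=100, set_id="P") -> PathwayProfile:
    return PathwayProfile(set_id=set_id, fractions=np.asarray(fractions, float),
                          n_scores=n_scores)


class TestBuildBinScheme:
    def test_even_pool_uniform_background(self):
        scheme = build_bin_scheme(np.linspace(0, 1, 1000), n_bins=10)
        assert np.allclose(scheme.background_fractions, 0.1)
        assert len(scheme.edges) == 11
        assert np.all(np.diff(scheme.edges) > 0)

    def test_all_identical_falls_back_single_bin(self, caplog):
        with caplog.at_level("WARNING"):
            scheme = build_bin_scheme(np.full(50, 0.7), n_bins=10)
        assert scheme.fallback_used
        assert np.sum(scheme.background_fractions > 0) == 1
        assert scheme.background_fractions.sum() == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            scheme = build_bin_scheme(rng.exponential(size=200), n_bins=10)
            assert scheme.background_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_quantile_background_near_uniform(self):
        rng = np.random.default_rng(1)
        scheme = build_bin_scheme(rng.normal(size=5000), n_bins=10)
        assert np.all(np.abs(scheme.background_fractions - 0.1) < 0.01)

    def test_equal_width_mode(self):
        scheme = build_bin_scheme(np.linspace(0, 1, 101), n_bins=10, mode="width")
        assert np.allclose(np.diff(scheme.edges), 0.1)

    def test_errors(self):
        with pytest.raises(ValueError):
            build_bin_scheme(np.array([]), n_bins=10)
        with pytest.raises(ValueError):
            build_bin_scheme(np.arange(10.0), n_bins=1)
        with pytest.raises(ValueError):
            build_bin_scheme(np.arange(10.0), mode="nope")

    def test_edge_assignment_conventions(self):
        scheme = build_bin_scheme(np.linspace(0, 1, 101), n_bins=10, mode="width")
        # left-closed/right-open; last bin right-closed; out-of-range clamps
        assert scheme.assign(np.array([0.0]))[0] == 0
        assert scheme.assign(np.array([0.1]))[0] == 1
        assert scheme.assign(np.array([1.0]))[0] == 9
        assert scheme.assign(np.array([-5.0]))[0] == 0
        assert scheme.assign(np.array([5.0]))[0] == 9


class TestXdScore:
    def test_identical_distributions_zero(self):
        scheme = uniform_scheme()
        prof = make_profile([0.1] * 10)
        assert xd_score(prof, scheme) == pytest.approx(0.0, abs=1e-9)

    def test_concentrated_near(self):
        scheme = uniform_scheme()
        prof = make_profile([1.0] + [0.0] * 9)
        expected = 0.9 - 0.1 * (H(10) - 1)  # = 0.707103...
        assert xd_score(prof, scheme) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.707103, abs=1e-6)

    def test_concentrated_far_negative(self):
        scheme = uniform_scheme()
        prof = make_profile([0.0] * 9 + [1.0])
        expected = -0.1 * H(9) + 0.09  # = -0.192897...
        assert xd_score(prof, scheme) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-0.192897, abs=1e-6)

    def test_empty_profile_nan(self):
        scheme = uniform_scheme()
        assert math.isnan(xd_score(make_profile([0.0] * 10, n_scores=0), scheme))

    def test_divide_by_n_flag(self):
        scheme = uniform_scheme()
        prof = make_profile([1.0] + [0.0] * 9)
        assert xd_score(prof, scheme, divide_by_n=True) == pytest.approx(
            xd_score(prof, scheme) / 10
        )

    def test_mass_shift_monotonicity(self):
        rng = np.random.default_rng(2)
        scheme = uniform_scheme()
        for _ in range(200):
            f = rng.dirichlet(np.ones(10))
            j = int(rng.integers(1, 10))
            i = int(rng.integers(0, j))
            if f[j] == 0:
                continue
            eps = f[j] * rng.uniform(0.1, 1.0)
            g = f.copy()
            g[j] -= eps
            g[i] += eps
            assert xd_score(make_profile(g), scheme) > xd_score(
                make_profile(f), scheme
            )

    def test_bounded_by_harmonic_number(self):
        rng = np.random.default_rng(3)
        scheme = uniform_scheme()
        for _ in range(200):
            prof = make_profile(rng.dirichlet(np.ones(10)))
            assert abs(xd_score(prof, scheme)) <= H(10)

    def test_background_self_score_zero(self):
        rng = np.random.default_rng(4)
        pooled = rng.beta(5, 1, size=700)
        scheme = build_bin_scheme(pooled, n_bins=10)
        prof = profile_scores(pooled, scheme)
        assert xd_score(prof, scheme) == pytest.approx(0.0, abs=1e-9)


class TestProfilePathway:
    def setup_method(self):
        self.net = Network.from_edges(
            [(f"G{i}", f"G{i + 1}", 1.0) for i in range(9)]
        )
        self.dv = DistanceVector({f"G{i}": i / 10 for i in range(10)})
        self.scheme = build_bin_scheme(
            np.array([i / 10 for i in range(10)]), n_bins=5, mode="width"
        )

    def _mapped(self, members):
        gs = GeneSet("R", "r", frozenset(members))
        return map_set(gs, self.net, min_mapped=1)

    def test_all_in_first_bin(self):
        prof = profile_pathway(
            DistanceVector({"G0": 0.0, "G1": 0.01}),
            self._mapped({"G0", "G1"}),
            self.scheme,
        )
        assert prof.fractions[0] == 1.0
        assert prof.fractions[1:].sum() == 0.0

    def test_tissue_filter_excluding_all_gives_empty(self):
        prof = profile_pathway(
            self.dv, self._mapped({"G0", "G1"}), self.scheme,
            tissue_filter={"G9"},
        )
        assert prof.empty

    def test_tissue_filter_all_nodes_is_identity(self):
        ms = self._mapped({"G0", "G3", "G7"})
        full = profile_pathway(self.dv, ms, self.scheme)
        filt = profile_pathway(self.dv, ms, self.scheme,
                               tissue_filter=set(self.net.nodes))
        assert np.array_equal(full.fractions, filt.fractions)
        assert full.n_scores == filt.n_scores

    def test_fractions_normalized(self):
        prof = profile_pathway(self.dv, self._mapped({"G0", "G5", "G9"}),
                               self.scheme)
        assert prof.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert prof.n_scores == 3


class TestScoreCollection:
    def _planted_net(self):
        """Target clique wired tightly; distractor set >= 3 hops away."""
        edges = []
        clique = ["T1", "T2", "T3", "T4"]
        for i, a in enumerate(clique):
            for b in clique[i + 1:]:
                edges.append((a, b, 0.9))
        # chain of bridges then the distractor blob
        edges += [("T4", "B1", 0.5), ("B1", "B2", 0.5), ("B2", "B3", 0.5)]
        distract = ["D1", "D2", "D3", "D4"]
        edges.append(("B3", "D1", 0.5))
        for i, a in enumerate(distract):
            for b in distract[i + 1:]:
                edges.append((a, b, 0.9))
        return Network.from_edges(edges)

    def test_self_reference_outranks_distant_set(self):
        net = self._planted_net()
        target = map_set(GeneSet("T", "t", frozenset({"T1", "T2", "T3", "T4"})),
                         net, min_mapped=1)
        ref_self = map_set(GeneSet("SELF", "s", frozenset({"T1", "T2", "T3", "T4"})),
                           net, min_mapped=1)
        ref_far = map_set(GeneSet("FAR", "f", frozenset({"D1", "D2", "D3", "D4"})),
                          net, min_mapped=1)
        res = score_collection(net, target, [ref_far, ref_self], n_bins=2)
        assert res[0].set_id == "SELF"
        assert res[0].xd > res[1].xd

    def test_identical_refs_identical_scores(self, small_bundle):
        b = small_bundle
        target = map_set(b.target, b.network, min_mapped=1)
        gs = b.pathways.sets[0]
        twin = GeneSet("TWIN", "copy", gs.members)
        refs = [map_set(gs, b.network, min_mapped=1),
                map_set(twin, b.network, min_mapped=1)]
        res = score_collection(b.network, target, refs)
        assert res[0].xd == res[1].xd

    def test_order_invariance(self, small_bundle):
        b = small_bundle
        target = map_set(b.target, b.network, min_mapped=1)
        refs = [map_set(gs, b.network, min_mapped=1) for gs in b.pathways]
        res_fwd = score_collection(b.network, target, refs)
        res_rev = score_collection(b.network, target, refs[::-1])
        assert [(r.set_id, r.xd) for r in res_fwd] == [
            (r.set_id, r.xd) for r in res_rev
        ]

    def test_unscorable_ref_gets_nan_and_sorts_last(self, small_bundle):
        b = small_bundle
        target = map_set(b.target, b.network, min_mapped=1)
        ghost = map_set(GeneSet("GHOST", "g", frozenset({"NOPE1", "NOPE2"})),
                        b.network, min_mapped=1)
        refs = [map_set(gs, b.network, min_mapped=1) for gs in b.pathways]
        res = score_collection(b.network, target, refs + [ghost])
        assert res[-1].set_id == "GHOST"
        assert math.isnan(res[-1].xd)

    def test_no_scorable_ref_errors(self, small_bundle):
        b = small_bundle
        target = map_set(b.target, b.network, min_mapped=1)
        ghost = map_set(GeneSet("GHOST", "g", frozenset({"NOPE"})),
                        b.network, min_mapped=1)
        with pytest.raises(ValueError):
            score_collection(b.network, target, [ghost])

    def test_tissue_scores_present(self, small_bundle):
        b = small_bundle
        target = map_set(b.target, b.network, min_mapped=1)
        refs = [map_set(gs, b.network, min_mapped=1) for gs in b.pathways]
        res = score_collection(b.network, target, refs, tissue=b.tissue)
        for r in res:
            assert r.tissue_scores is not None
            assert set(r.tissue_scores) == set(b.tissue.tissues())


class TestTissueRestriction:
    def test_single_tissue_covering_everything_matches_global(self, small_bundle):
        b = small_bundle
        target = map_set(b.target, b.network, min_mapped=1)
        refs = [map_set(gs, b.network, min_mapped=1) for gs in b.pathways]
        ann = TissueAnnotation({n: {"everywhere"} for n in b.network.nodes})
        res = score_collection(b.network, target, refs, tissue=ann)
        for r in res:
            assert r.tissue_scores["everywhere"] == r.xd

    def test_excluded_pathway_not_scorable_in_tissue(self, small_bundle):
        b = small_bundle
        target = map_set(b.target, b.network, min_mapped=1)
        refs = [map_set(gs, b.network, min_mapped=1) for gs in b.pathways]
        excluded = b.pathways.sets[0].members
        ann = TissueAnnotation(
            {n: {"somewhere"} for n in b.network.nodes if n not in excluded}
        )
        res = score_collection(b.network, target, refs, tissue=ann)
        by_id = {r.set_id: r for r in res}
        assert math.isnan(by_id[b.pathways.sets[0].set_id].tissue_scores["somewhere"])
        # other pathways are still scorable there
        assert any(
            not math.isnan(r.tissue_scores["somewhere"])
            for r in res if r.set_id != b.pathways.sets[0].set_id
        )


class TestCompareTissueGroups:
    def test_basic(self):
        scores = {f"a{i}": 0.5 + 0.01 * i for i in range(6)}
        scores.update({f"b{i}": 0.01 * i for i in range(6)})
        u, p = compare_tissue_groups(
            scores, {f"a{i}" for i in range(6)}, {f"b{i}" for i in range(6)},
            alternative="greater",
        )
        assert p < 0.01

    def test_nan_dropped_and_empty_group_errors(self):
        scores = {"a": math.nan, "b": 0.2}
        with pytest.raises(ValueError):
            compare_tissue_groups(scores, {"a"}, {"b"})
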
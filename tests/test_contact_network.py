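import itertools
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perchwatch import contact_network as cn
from perchwatch.contact_network import InteractionKind

from conftest import bird, visit


def classify_oracle(a_start, a_end, b_start, b_end):
    """Interval-arithmetic oracle: returns 'LONG', 'TRANSIENT' or None."""
    overlap = max(0, min(a_end, b_end) - max(a_start, b_start))
    if overlap > 11:
        return "LONG"
    earlier_end, later_start = (
        (a_end, b_start) if (a_start, a_end) <= (b_start, b_end) else (b_end, a_start)
    )
    if later_start - earlier_end < 11:
        return "TRANSIENT"
    return None


class TestClassifyVisitPair:
    @pytest.mark.parametrize(
        "a,b,kind,overlap",
        [
            ((0, 30), (10, 25), InteractionKind.LONG, 15),
            ((0, 30), (40, 45), InteractionKind.TRANSIENT, 0),
            ((0, 5), (100, 110), None, None),
            ((0, 30), (20, 25), InteractionKind.TRANSIENT, 5),  # overlap in (0,11]
        ],
    )
    def test_examples(self, a, b, kind, overlap):
        out = cn.classify_visit_pair(visit("A", *a), visit("B", *b))
        if kind is None:
            assert out is None
        else:
            assert out.kind is kind
            assert out.overlap_s == overlap

    def test_gap_exactly_eleven_is_no_interaction(self):
        assert cn.classify_visit_pair(visit("A", 0, 30), visit("B", 41, 45)) is None

    def test_gap_just_under_eleven_interacts(self):
        out = cn.classify_visit_pair(visit("A", 0, 30), visit("B", 40, 45))
        assert out is not None and out.gap_s == 10

    def test_overlap_exactly_eleven_is_transient(self):
        out = cn.classify_visit_pair(visit("A", 0, 30), visit("B", 10, 21))
        assert out.kind is InteractionKind.TRANSIENT

    def test_same_bird_never_interacts(self):
        assert cn.classify_visit_pair(visit("A", 0, 30), visit("A", 10, 25)) is None

    def test_different_stations_never_interact(self):
        assert cn.classify_visit_pair(
            visit("A", 0, 30, station="S1"), visit("B", 10, 25, station="S2")
        ) is None

    @given(
        a=st.tuples(st.integers(0, 200), st.integers(0, 100)),
        b=st.tuples(st.integers(0, 200), st.integers(0, 100)),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_interval_oracle(self, a, b):
        a0, a1 = a[0], a[0] + a[1]
        b0, b1 = b[0], b[0] + b[1]
        out = cn.classify_visit_pair(visit("A", a0, a1), visit("B", b0, b1))
        expected = classify_oracle(a0, a1, b0, b1)
        assert (None if out is None else out.kind.value) == expected


class TestDetectInteractions:
    def test_symmetry_under_input_order(self):
        vs = [visit("A", 0, 30), visit("B", 10, 25), visit("C", 50, 60)]
        assert cn.detect_interactions(vs) == cn.detect_interactions(vs[::-1])

    def test_long_visit_interacts_with_multiple_partners(self):
        vs = [visit("A", 0, 100), visit("B", 10, 30), visit("C", 60, 80)]
        out = cn.detect_interactions(vs)
        pairs = {(i.bird_a, i.bird_b) for i in out}
        assert ("A", "B") in pairs and ("A", "C") in pairs

    def test_matches_all_pairs_enumeration(self):
        rng = np.random.default_rng(17)
        vs = []
        for k in range(40):
            s = int(rng.integers(0, 600))
            vs.append(visit(f"T{k % 8}", s, s + int(rng.integers(0, 60))))
        fast = cn.detect_interactions(vs)
        slow = []
        for v1, v2 in itertools.combinations(vs, 2):
            out = cn.classify_visit_pair(v1, v2)
            if out is not None:
                slow.append(out)
        assert sorted(fast, key=repr) == sorted(slow, key=repr)

    def test_canonical_ordering(self):
        out = cn.detect_interactions([visit("Z", 0, 30), visit("A", 10, 25)])
        assert out[0].bird_a == "A" and out[0].bird_b == "Z"


class TestBuildNetwork:
    def _interactions(self, specs):
        vs = []
        for i, (a, b, a_span, b_span) in enumerate(specs):
            base_off = 10000 * i
            vs.append(visit(a, base_off + a_span[0], base_off + a_span[1]))
            vs.append(visit(b, base_off + b_span[0], base_off + b_span[1]))
        return cn.detect_interactions(vs)

    def test_transient_edge_weight_zero(self):
        inter = self._interactions(
            [("A", "B", (0, 0), (5, 5)), ("A", "B", (0, 0), (5, 5)),
             ("A", "B", (0, 0), (5, 5))]
        )
        g = cn.build_network(inter)
        assert g["A"]["B"]["n_interactions"] == 3
        assert g["A"]["B"]["weight_s"] == 0

    def test_weights_sum(self):
        inter = self._interactions(
            [("A", "B", (0, 30), (10, 25)), ("A", "B", (0, 40), (15, 35))]
        )
        g = cn.build_network(inter)
        assert g["A"]["B"]["weight_s"] == 15 + 20

    def test_empty(self):
        g = cn.build_network([])
        assert g.number_of_nodes() == 0

    def test_node_attributes_from_roster(self):
        inter = self._interactions([("A", "B", (0, 30), (10, 25))])
        g = cn.build_network(inter, [bird("A"), bird("B")])
        assert g.nodes["A"]["sex"] == "F"

    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)), max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_degree_sum_is_twice_edges(self, pairs):
        g = nx.Graph()
        g.add_nodes_from(range(6))
        for a, b in pairs:
            if a != b:
                g.add_edge(a, b, weight_s=1, n_interactions=1)
        degrees = cn.centralities(g)["degree"]
        assert degrees.sum() == 2 * g.number_of_edges()


def betweenness_oracle(g: nx.Graph) -> dict:
    """Exhaustive all-pairs shortest-path enumeration (unweighted)."""
    nodes = list(g.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        # enumerate all shortest s-t paths by BFS layering
        paths = []
        best = None
        queue = deque([(s, (s,))])
        while queue:
            node, path = queue.popleft()
            if best is not None and len(path) > best:
                continue
            if node == t:
                if best is None:
                    best = len(path)
                if len(path) == best:
                    paths.append(path)
                continue
            for nb in g.neighbors(node):
                if nb not in path:
                    queue.append((nb, path + (nb,)))
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: (score[v] / norm if norm > 0 else 0.0) for v in nodes}


class TestCentralities:
    def test_star(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        out = cn.centralities(g)
        assert out.loc[0, "degree"] == 4
        assert out.loc[0, "betweenness"] == pytest.approx(1.0)
        assert all(out.loc[leaf, "betweenness"] == 0 for leaf in range(1, 5))

    def test_complete_graph(self):
        out = cn.centralities(nx.complete_graph(4))
        assert (out["betweenness"] == 0).all()

    def test_path(self):
        out = cn.centralities(nx.path_graph(3))
        assert out.loc[1, "betweenness"] == pytest.approx(1.0)

    def test_empty_network_is_error(self):
        with pytest.raises(ValueError):
            cn.centralities(nx.Graph())

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_oracle_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(0, 2**31)))
        if g.number_of_nodes() == 0:
            return
        out = cn.centralities(g)
        oracle = betweenness_oracle(g)
        for v in g.nodes:
            assert out.loc[v, "betweenness"] == pytest.approx(oracle[v], abs=1e-12)


class TestComponents:
    def test_empty(self):
        assert cn.components(nx.Graph()) == []

    def test_two_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("c", "a"),
                          ("x", "y"), ("y", "z"), ("z", "x")])
        comps = cn.components(g)
        assert [len(c) for c in comps] == [3, 3]

    def test_union_find_oracle(self):
        rng = np.random.default_rng(9)
        g = nx.gnp_random_graph(30, 0.05, seed=4)
        comps = cn.components(g)
        # union-find oracle
        parent = list(range(30))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in g.edges:
            parent[find(a)] = find(b)
        groups = {}
        for v in g.nodes:
            groups.setdefault(find(v), set()).add(v)
        assert set(map(frozenset, comps)) == set(map(frozenset, groups.values()))

    def test_three_site_colony_three_components(self):
        # no cross-site interactions -> one component per site
        vs = []
        for i, station in enumerate(("S1", "S2", "S3")):
            base_off = 100000 * i
            vs.append(visit(f"a{i}", base_off, base_off + 30, station=station))
            vs.append(visit(f"b{i}", base_off + 5, base_off + 25, station=station))
        g = cn.build_network(cn.detect_interactions(vs))
        assert len(cn.components(g)) == 3


class TestPermutationGLM:
    def _attrs(self, sexes, ages=None):
        ages = ages or ["AHY"] * len(sexes)
        return pd.DataFrame({"sex": sexes, "age": ages})

    def test_constant_response_p_one(self):
        attrs = self._attrs(["F", "M", "F", "M"], ["AHY", "HY", "AHY", "HY"])
        res = cn.permutation_glm([3.0] * 4, attrs, n_perm=200, seed=0)
        for c in res.coefficients.values():
            assert c["beta"] == pytest.approx(0.0)
            assert c["p_perm"] == pytest.approx(1.0)

    def test_constant_predictor_undefined(self):
        attrs = self._attrs(["F", "F", "F"], ["AHY", "HY", "AHY"])
        res = cn.permutation_glm([1.0, 2.0, 3.0], attrs, n_perm=50, seed=0)
        assert res.coefficients["sex"]["defined"] is False
        assert np.isnan(res.coefficients["sex"]["beta"])

    def test_p_never_below_add_one_bound(self):
        attrs = self._attrs(["F", "M"] * 5)
        rng = np.random.default_rng(0)
        res = cn.permutation_glm(rng.normal(size=10), attrs,
                                 predictors=("sex",), n_perm=99, seed=1)
        assert res.coefficients["sex[M]"]["p_perm"] >= 1 / 100

    def test_seed_reproducible(self):
        attrs = self._attrs(["F", "M"] * 6)
        y = np.arange(12.0)
        a = cn.permutation_glm(y, attrs, predictors=("sex",), n_perm=500, seed=42)
        b = cn.permutation_glm(y, attrs, predictors=("sex",), n_perm=500, seed=42)
        assert a.coefficients == b.coefficients

    def test_sampled_p_close_to_exhaustive_enumeration(self):
        # 6 nodes, binary trait: enumerate all 6! label reorderings exactly
        y = np.array([0.1, 2.0, 1.3, 4.0, 0.2, 3.1])
        trait = ["F", "F", "F", "M", "M", "M"]
        attrs = self._attrs(trait)
        X = np.column_stack([np.ones(6), np.array([s == "M" for s in trait], float)])
        pinv = np.linalg.pinv(X)
        beta_obs = (pinv @ y)[1]
        count = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            Xp = X[list(perm)]
            b = (np.linalg.pinv(Xp) @ y)[1]
            count += abs(b) >= abs(beta_obs) - 1e-12
            total += 1
        exact = count / total
        res = cn.permutation_glm(y, attrs, predictors=("sex",), n_perm=5000, seed=3)
        assert res.coefficients["sex[M]"]["p_perm"] == pytest.approx(exact, abs=0.02)

    def test_type_i_error_rate(self):
        # trait independent of the response: rejection rate ~ alpha
        rng = np.random.default_rng(100)
        n_rep, rejections = 500, 0
        for k in range(n_rep):
            y = rng.normal(size=20)
            attrs = self._attrs(list(rng.choice(["F", "M"], size=20)))
            if attrs["sex"].nunique() < 2:
                continue
            res = cn.permutation_glm(y, attrs, predictors=("sex",),
                                     n_perm=199, seed=k)
            rejections += res.coefficients["sex[M]"]["p_perm"] <= 0.05
        from scipy import stats
        lo, hi = stats.binom.ppf([0.005, 0.995], n_rep, 0.05)
        assert lo <= rejections <= hi
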
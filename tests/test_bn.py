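"""Bayesian network: enumeration, scoring, search, and equivalence classes."""
import itertools

import numpy as np
import pytest

from triplenet.bn import (
    DAGStructure,
    GaussianBN,
    SuffStats,
    bic_score,
    cpdag_of,
    enumerate_dags,
    extract_network_timeseries,
    fit_mle,
    learn_structure_exhaustive,
    learn_structure_l1paths,
)
from triplenet.cohort import SubjectBold, default_hub_model, \
    simulate_node_timecourses


def brute_force_dag_count(n):
    """Oracle: filter all off-diagonal binary matrices for acyclicity using
    an independent check (matrix power series)."""
    positions = [(i, j) for i in range(n) for j in range(n) if i != j]
    count = 0
    for code in range(2 ** len(positions)):
        adj = np.zeros((n, n))
        for bit, (i, j) in enumerate(positions):
            if code >> bit & 1:
                adj[i, j] = 1
        # acyclic iff no positive diagonal in any power A^k, k=1..n
        acyclic = True
        power = np.eye(n)
        for _ in range(n):
            power = power @ adj
            if np.trace(power) > 0:
                acyclic = False
                break
        count += acyclic
    return count


def sem_sample(adj_weights, n, seed, noise_sd=1.0):
    """Draw from a linear-Gaussian structural equation model."""
    rng = np.random.default_rng(seed)
    k = adj_weights.shape[0]
    e = rng.standard_normal((n, k)) * noise_sd
    x = np.zeros((n, k))
    done, order = set(), []
    while len(order) < k:  # topological order of the weight DAG
        for j in range(k):
            parents = set(np.nonzero(adj_weights[:, j])[0])
            if j not in done and parents <= done:
                order.append(j)
                done.add(j)
    for j in order:
        x[:, j] = x @ adj_weights[:, j] + e[:, j]
    return x


class TestEnumeration:
    @pytest.mark.parametrize("n, expected", [(2, 3), (3, 25), (4, 543)])
    def test_counts_match_brute_force(self, n, expected):
        dags = enumerate_dags(n)
        assert len(dags) == expected
        assert brute_force_dag_count(n) == expected
        assert len({d.adjacency for d in dags}) == expected  # each once

    def test_canonical_order_is_deterministic(self):
        assert [d.adjacency for d in enumerate_dags(3)] == \
            [d.adjacency for d in enumerate_dags(3)]

    def test_capacity_guard(self):
        with pytest.raises(ValueError, match="L1"):
            enumerate_dags(6)


class TestFitMle:
    def test_noiseless_edge_recovers_weight_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        data = np.column_stack([x, 0.5 * x])
        structure = DAGStructure.from_matrix(("X", "Y"), [[0, 1], [0, 0]])
        model = fit_mle(structure, data)
        assert model.weights[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert model.noise_variances[1] == pytest.approx(0, abs=1e-10)

    def test_empty_graph_variances_are_column_variances(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((500, 3)) * np.array([1.0, 2.0, 0.5])
        structure = DAGStructure.from_matrix(("A", "B", "C"), np.zeros((3, 3)))
        model = fit_mle(structure, data)
        assert model.structure.n_edges == 0
        np.testing.assert_allclose(model.noise_variances,
                                   data.var(axis=0), atol=1e-12)

    def test_planted_weight_within_three_se(self):
        # oracle: closed-form OLS on the generated sample
        w = np.zeros((3, 3))
        w[2, 0] = 0.6  # SN -> CEN with columns (CEN, DMN, SN)
        data = sem_sample(w, 2000, seed=2)
        structure = DAGStructure.from_matrix(
            ("CEN", "DMN", "SN"), (w != 0).astype(int))
        model = fit_mle(structure, data)
        se = 1.0 / np.sqrt(2000)
        assert abs(model.weights[2, 0] - 0.6) < 3 * se


class TestBicScore:
    def test_two_node_score_equivalence(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(400)
        data = np.column_stack([x, 0.7 * x + rng.standard_normal(400)])
        fwd = DAGStructure.from_matrix(("X", "Y"), [[0, 1], [0, 0]])
        rev = DAGStructure.from_matrix(("X", "Y"), [[0, 0], [1, 0]])
        assert bic_score(fwd, data) == pytest.approx(bic_score(rev, data),
                                                     abs=1e-8)

    def test_penalty_rejects_spurious_edge(self):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((1000, 3))
        empty = DAGStructure.from_matrix(("A", "B", "C"), np.zeros((3, 3)))
        s_empty = bic_score(empty, data)
        for i, j in itertools.permutations(range(3), 2):
            adj = np.zeros((3, 3), dtype=int)
            adj[i, j] = 1
            one = DAGStructure.from_matrix(("A", "B", "C"), adj)
            assert s_empty > bic_score(one, data)

    def test_true_edge_beats_empty(self):
        w = np.zeros((2, 2))
        w[0, 1] = 0.8
        data = sem_sample(w, 500, seed=5)
        edge = DAGStructure.from_matrix(("X", "Y"), [[0, 1], [0, 0]])
        empty = DAGStructure.from_matrix(("X", "Y"), np.zeros((2, 2)))
        assert bic_score(edge, data) > bic_score(empty, data)

    def test_score_equivalence_across_all_three_node_classes(self):
        """BIC agrees within 1e-8 on every Markov-equivalent pair.

        The oracle groups the 25 three-node DAGs by skeleton+v-structure
        (computed here, independently of the package's CPDAG code).
        """
        def vstructs(adj):
            out = set()
            skel = ((adj + adj.T) > 0)
            for c in range(3):
                ps = np.nonzero(adj[:, c])[0]
                for a, b in itertools.combinations(ps, 2):
                    if not skel[a, b]:
                        out.add((min(a, b), max(a, b), c))
            return frozenset(out)

        def skel_key(adj):
            return tuple(map(tuple, ((adj + adj.T) > 0).astype(int)))

        dags = enumerate_dags(3)
        rng = np.random.default_rng(6)
        for _ in range(3):
            data = sem_sample(np.triu(rng.uniform(-1, 1, (3, 3)), 1),
                              300, seed=rng.integers(2**31))
            scores = [bic_score(d, data) for d in dags]
            for i, j in itertools.combinations(range(len(dags)), 2):
                ai, aj = dags[i].matrix, dags[j].matrix
                if skel_key(ai) == skel_key(aj) and \
                        vstructs(ai) == vstructs(aj):
                    assert abs(scores[i] - scores[j]) < 1e-8


class TestExhaustiveSearch:
    def test_independent_columns_select_empty_graph(self):
        rng = np.random.default_rng(7)
        model, _ = learn_structure_exhaustive(rng.standard_normal((800, 3)))
        assert model.structure.n_edges == 0

    def test_planted_collider_is_identified(self):
        # v-structure CEN -> SN <- DMN is the unique member of its class
        w = np.zeros((3, 3))
        w[0, 2] = w[1, 2] = 0.7  # columns (CEN, DMN, SN)
        data = sem_sample(w, 1000, seed=8)
        model, report = learn_structure_exhaustive(data)
        assert set(model.structure.edges()) == {("CEN", "SN"), ("DMN", "SN")}
        assert len(report["ties"]) == 1
        # oracle: independent recomputation of every score
        dags = enumerate_dags(3, nodes=("CEN", "DMN", "SN"))
        scores = [bic_score(d, data) for d in dags]
        assert model.bic == pytest.approx(max(scores), abs=1e-9)

    def test_planted_hub_recovers_equivalence_class(self):
        w = np.zeros((3, 3))
        w[2, 0], w[2, 1] = 0.6, 0.5  # SN -> CEN, SN -> DMN
        data = sem_sample(w, 1000, seed=9)
        model, report = learn_structure_exhaustive(data)
        truth = DAGStructure.from_matrix(("CEN", "DMN", "SN"),
                                         (w != 0).astype(int))
        # winner lies in the hub's 3-member class; skeleton SN-CEN, SN-DMN
        assert len(report["ties"]) == 3
        cp = report["cpdag"]
        assert set(cp.skeleton_edges()) == {("CEN", "SN"), ("DMN", "SN")}
        assert cp.directed_edges() == []  # no collider: nothing compelled
        from triplenet.bn import markov_equivalent
        assert markov_equivalent(model.structure, truth)


class TestL1Paths:
    def test_matches_exhaustive_on_planted_data(self):
        rng = np.random.default_rng(10)
        for rep in range(20):
            w = np.triu(rng.uniform(-0.9, 0.9, (3, 3)), 1) * \
                rng.integers(0, 2, (3, 3))
            data = sem_sample(w, 500, seed=int(rng.integers(2**31)))
            data = data[:, rng.permutation(3)]
            me, _ = learn_structure_exhaustive(data)
            ml, _ = learn_structure_l1paths(data)
            assert ml.bic == pytest.approx(me.bic, abs=1e-6)

    def test_infinite_lambda_gives_empty_graph(self):
        rng = np.random.default_rng(11)
        data = sem_sample(np.array([[0, 0.8, 0], [0, 0, 0.5], [0, 0, 0]],
                                   float), 400, seed=12)
        model, _ = learn_structure_l1paths(data, lambda_grid=[1e9])
        assert model.structure.n_edges == 0

    def test_collider_cpdag_matches_exhaustive(self):
        w = np.zeros((3, 3))
        w[0, 2] = w[1, 2] = 0.7
        data = sem_sample(w, 800, seed=13)
        _, re = learn_structure_exhaustive(data)
        _, rl = learn_structure_l1paths(data)
        assert re["cpdag"] == rl["cpdag"]

    def test_empty_lambda_grid_raises(self):
        with pytest.raises(ValueError):
            learn_structure_l1paths(np.zeros((50, 3)), lambda_grid=[])


class TestCpdag:
    def test_collider_fully_compelled(self):
        dag = DAGStructure.from_matrix(("X", "Y", "Z"),
                                       [[0, 0, 1], [0, 0, 1], [0, 0, 0]])
        cp = cpdag_of(dag)
        assert set(cp.directed_edges()) == {("X", "Z"), ("Y", "Z")}
        assert cp.undirected_edges() == []

    def test_chain_fully_reversible(self):
        dag = DAGStructure.from_matrix(("X", "Y", "Z"),
                                       [[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        cp = cpdag_of(dag)
        assert cp.directed_edges() == []
        assert set(cp.undirected_edges()) == {("X", "Y"), ("Y", "Z")}

    def test_empty_graph(self):
        dag = DAGStructure.from_matrix(("X", "Y", "Z"), np.zeros((3, 3)))
        cp = cpdag_of(dag)
        assert cp.directed_edges() == [] and cp.undirected_edges() == []

    def test_meek_rule_orients_descendant_of_collider(self):
        # X -> Z <- Y plus Z -> W: Z -> W is compelled by Meek R1
        dag = DAGStructure.from_matrix(
            ("X", "Y", "Z", "W"),
            [[0, 0, 1, 0], [0, 0, 1, 0], [0, 0, 0, 1], [0, 0, 0, 0]])
        cp = cpdag_of(dag)
        assert ("Z", "W") in cp.directed_edges()

    def test_classes_match_distribution_equivalence(self):
        """CPDAG equality on all 25 three-node DAGs reproduces the grouping
        induced by BIC equality on random data (distribution equivalence)."""
        dags = enumerate_dags(3)
        rng = np.random.default_rng(14)
        data = sem_sample(np.triu(rng.uniform(0.4, 0.9, (3, 3)), 1), 400,
                          seed=15)
        scores = np.array([bic_score(d, data) for d in dags])
        cpdags = [cpdag_of(d) for d in dags]
        for i, j in itertools.combinations(range(25), 2):
            same_class = cpdags[i] == cpdags[j]
            same_score = abs(scores[i] - scores[j]) < 1e-8
            if same_class:
                assert same_score
        # and the number of classes is the known 11 for three nodes
        assert len(set(cpdags)) == 11


class TestExtractTimeseries:
    def _bold(self, data):
        return SubjectBold(data=data, mask=np.ones(data.shape[:3], bool),
                           tr_seconds=2.5, subject_id="s", group="HR")

    def test_singleton_mask_returns_standardized_voxel(self):
        rng = np.random.default_rng(16)
        data = rng.standard_normal((4, 4, 2, 60))
        masks = {}
        for i, name in enumerate(("CEN", "DMN", "SN")):
            m = np.zeros((4, 4, 2), bool)
            m[i, 0, 0] = True
            masks[name] = m
        x = extract_network_timeseries(self._bold(data), masks)
        v = data[0, 0, 0]
        np.testing.assert_allclose(x[:, 0], (v - v.mean()) / v.std(),
                                   atol=1e-12)

    def test_cancelling_voxels_raise_degenerate_variance(self):
        data = np.zeros((2, 1, 1, 30))
        s = np.sin(np.arange(30))
        data[0, 0, 0] = s
        data[1, 0, 0] = -s
        masks = {n: np.ones((2, 1, 1), bool) for n in ("CEN", "DMN", "SN")}
        with pytest.raises(ValueError, match="zero-variance"):
            extract_network_timeseries(self._bold(data), masks)

    def test_empty_mask_names_network(self):
        data = np.random.default_rng(17).standard_normal((3, 3, 3, 20))
        masks = {"CEN": np.ones((3, 3, 3), bool),
                 "DMN": np.zeros((3, 3, 3), bool),
                 "SN": np.ones((3, 3, 3), bool)}
        with pytest.raises(ValueError, match="DMN"):
            extract_network_timeseries(self._bold(data), masks)

    def test_planted_cohort_recovers_node_series(self, tiny_cohort):
        subjects, truth = tiny_cohort
        bold = subjects[0]
        x = extract_network_timeseries(bold, truth.masks)
        sn = truth.node_series[bold.subject_id]["SN"].to_numpy()
        r = np.corrcoef(x[:, 2], sn)[0, 1]
        assert r > 0.9


def test_estimator_api_roundtrip():
    rng = np.random.default_rng(18)
    w = np.zeros((3, 3))
    w[2, 0], w[2, 1] = 0.6, 0.5
    data = sem_sample(w, 600, seed=19)
    est = GaussianBN(search="exhaustive")
    assert est.get_params()["search"] == "exhaustive"
    est.fit(data)
    assert est.bic_ == pytest.approx(est.model_.bic)
    assert est.structure_.n_edges == 2
    clone_params = est.get_params()
    est2 = GaussianBN(**clone_params).fit(data)
    assert est2.structure_ == est.structure_
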
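"""Nodal reconfiguration metrics against definitional enumeration oracles."""

import numpy as np
import pytest

from dynconn import (
    AllegianceMatrix,
    MultilayerPartition,
    ValidationError,
    allegiance,
    classify_roles,
    flexibility,
    integration,
    node_metric_table,
    participation_coefficient,
    promiscuity,
    recruitment,
    within_module_degree,
)


def random_partition(rng, n=8, L=5, k=3):
    return MultilayerPartition(labels=rng.integers(1, k + 1, size=(n, L)))


def random_allegiance(rng, n=8):
    a = rng.random((n, n))
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 1.0)
    return AllegianceMatrix(values=a, n_layers=10)


# --- enumeration oracles -----------------------------------------------------

def oracle_allegiance(labels):
    n, L = labels.shape
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            out[j, k] = sum(labels[j, t] == labels[k, t] for t in range(L)) / L
    return out


def oracle_flexibility(labels):
    n, L = labels.shape
    return np.array(
        [sum(labels[i, t] != labels[i, t + 1] for t in range(L - 1)) / (L - 1)
         for i in range(n)]
    )


def oracle_promiscuity(labels):
    total = len(set(labels.ravel()))
    return np.array([len(set(row)) / total for row in labels])


def oracle_integration(a, ref):
    n = len(ref)
    out = np.empty(n)
    for i in range(n):
        others = [j for j in range(n) if ref[j] != ref[i]]
        out[i] = np.mean([a[i, j] for j in others])
    return out


def oracle_recruitment(a, ref):
    n = len(ref)
    out = np.empty(n)
    for i in range(n):
        own = [j for j in range(n) if ref[j] == ref[i] and j != i]
        out[i] = np.mean([a[i, j] for j in own]) if own else np.nan
    return out


def oracle_participation(a, ref):
    n = len(ref)
    out = np.empty(n)
    for i in range(n):
        k_is = {}
        for j in range(n):
            if j == i:
                continue
            k_is[ref[j]] = k_is.get(ref[j], 0.0) + a[i, j]
        k_i = sum(k_is.values())
        out[i] = 1.0 - sum((v / k_i) ** 2 for v in k_is.values())
    return out


def oracle_z(a, ref):
    n = len(ref)
    out = np.empty(n)
    for c in set(ref):
        members = [i for i in range(n) if ref[i] == c]
        if len(members) < 2:  # singleton module: flagged missing
            out[members[0]] = np.nan
            continue
        ks = [sum(a[i, j] for j in members if j != i) for i in members]
        mu, sd = np.mean(ks), np.std(ks)
        for i, k in zip(members, ks):
            out[i] = 0.0 if sd == 0 else (k - mu) / sd
    return out


# --- tests -------------------------------------------------------------------

def test_counting_metrics_match_enumeration(rng):
    """Allegiance, flexibility and promiscuity agree exactly with direct
    definitional counting on random partitions (n <= 10, L <= 6)."""
    for _ in range(10):
        n = int(rng.integers(3, 11))
        L = int(rng.integers(2, 7))
        p = random_partition(rng, n=n, L=L, k=int(rng.integers(2, 5)))
        assert np.allclose(allegiance(p).values, oracle_allegiance(p.labels))
        assert np.allclose(flexibility(p), oracle_flexibility(p.labels))
        assert np.allclose(promiscuity(p), oracle_promiscuity(p.labels))


def test_weighted_metrics_match_enumeration(rng):
    for _ in range(10):
        n = int(rng.integers(4, 11))
        al = random_allegiance(rng, n)
        ref = rng.integers(1, 4, size=n)
        if len(np.unique(ref)) < 2:
            continue
        assert np.allclose(integration(al, ref), oracle_integration(al.values, ref),
                           atol=1e-10)
        rec = recruitment(al, ref)
        want = oracle_recruitment(al.values, ref)
        assert np.allclose(rec, want, atol=1e-10, equal_nan=True)
        assert np.allclose(participation_coefficient(al, ref),
                           oracle_participation(al.values, ref), atol=1e-10)
        assert np.allclose(within_module_degree(al, ref),
                           oracle_z(al.values, ref), atol=1e-10,
                           equal_nan=True)


def test_allegiance_trivial_and_counted_cases():
    lab = np.ones((2, 28), dtype=int)
    lab[1, 14:] = 2  # co-assigned 14 of 28 layers
    a = allegiance(MultilayerPartition(labels=lab)).values
    assert a[0, 1] == pytest.approx(0.5)
    assert a[0, 0] == 1.0
    never = np.array([[1] * 5, [2] * 5])
    assert allegiance(MultilayerPartition(labels=never)).values[0, 1] == 0.0


def test_flexibility_examples():
    assert flexibility(
        MultilayerPartition(labels=np.array([[1, 1, 2, 2, 2]]))
    )[0] == pytest.approx(0.25)
    const = MultilayerPartition(labels=np.ones((3, 6), dtype=int))
    assert np.all(flexibility(const) == 0.0)
    alt = MultilayerPartition(labels=np.array([[1, 2, 1, 2]]))
    assert flexibility(alt)[0] == 1.0
    with pytest.raises(ValidationError):
        flexibility(MultilayerPartition(labels=np.ones((3, 1), dtype=int)))


def test_promiscuity_examples():
    labels = np.array([[1, 1, 2, 2], [1, 1, 1, 1], [1, 2, 3, 4]])
    out = promiscuity(MultilayerPartition(labels=labels))
    assert np.allclose(out, [0.5, 0.25, 1.0])
    single = MultilayerPartition(labels=np.ones((4, 3), dtype=int))
    assert np.all(promiscuity(single) == 1.0)


def test_observed_equals_reference_consistency():
    """When every layer reproduces the reference, recruitment is exactly 1
    and integration exactly 0."""
    ref = np.array([1, 1, 2, 2, 3, 3])
    labels = np.tile(ref[:, None], (1, 7))
    al = allegiance(MultilayerPartition(labels=labels))
    assert np.allclose(recruitment(al, ref), 1.0)
    assert np.allclose(integration(al, ref), 0.0)


def test_all_one_observed_community_integrates_fully():
    labels = np.ones((6, 5), dtype=int)
    al = allegiance(MultilayerPartition(labels=labels))
    ref = np.array([1, 1, 1, 2, 2, 2])
    assert np.allclose(integration(al, ref), 1.0)


def test_participation_uniform_spread_is_one_minus_inv_n():
    """Equal allegiance strength to each of N = 4 reference communities
    gives P = 1 - 4 (1/4)^2 = 0.75."""
    ref = np.repeat([1, 2, 3, 4], 3)  # 3 members each
    n = len(ref)
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # strengths per community equalised for node 0
            a[i, j] = 0.3 if ref[j] == ref[i] else 0.2
    np.fill_diagonal(a, 1.0)
    al = AllegianceMatrix(values=a, n_layers=10)
    # node 0: own community 2 * 0.3 = 0.6; others 3 * 0.2 = 0.6 each
    p = participation_coefficient(al, ref)
    assert p[0] == pytest.approx(0.75)


def test_participation_degenerate_cases():
    ref = np.array([1, 1, 2, 2])
    a = np.eye(4)
    al = AllegianceMatrix(values=a, n_layers=5)
    with pytest.warns(UserWarning, match="zero allegiance"):
        p = participation_coefficient(al, ref)
    assert np.all(p == 0.0)
    # single reference community -> single-term sum -> 0
    full = AllegianceMatrix(values=np.full((4, 4), 0.5) + 0.5 * np.eye(4),
                            n_layers=5)
    assert np.allclose(participation_coefficient(full, np.ones(4, int)), 0.0)


def test_within_module_degree_hand_case():
    """In-module strengths (2, 1.5, 0.5) standardise with the population-SD
    convention."""
    a = np.array(
        [[1, 1.0, 1.0, 0], [1.0, 1, 0.5, 0], [1.0, 0.5, 1, 0], [0, 0, 0, 1]]
    ) / 2.0
    np.fill_diagonal(a, 1.0)
    ref = np.array([1, 1, 1, 2])
    with pytest.warns(UserWarning, match="singleton"):
        z = within_module_degree(AllegianceMatrix(values=a, n_layers=4), ref)
    k = np.array([1.0, 0.75, 0.75])
    want = (k - k.mean()) / k.std()
    assert np.allclose(z[:3], want)
    assert np.isnan(z[3])


def test_within_module_degree_uniform_module_is_zero():
    a = np.full((4, 4), 0.5)
    np.fill_diagonal(a, 1.0)
    z = within_module_degree(AllegianceMatrix(values=a, n_layers=5),
                             np.ones(4, int))
    assert np.all(z == 0.0)


def test_role_percentile_rules():
    z = np.linspace(0, 1, 100)
    p = np.linspace(1, 0, 100)
    roles = classify_roles(z, p)
    assert np.all(roles[z >= np.percentile(z, 95)] == "hub")
    # low z / high p half are integrators
    assert (roles == "integrator").sum() == 50
    # node with high z but low p is 'other'
    z2 = np.array([0.6, 0.1, 0.9, 0.2, 0.5])
    p2 = np.array([0.1, 0.9, 0.9, 0.8, 0.5])
    roles2 = classify_roles(z2, p2)
    assert roles2[2] == "hub"
    assert roles2[1] == "integrator"
    assert roles2[0] == "other"


def test_roles_with_missing_values_warn():
    z = np.array([0.1, np.nan, 0.9, 0.5])
    p = np.array([0.5, 0.5, 0.5, 0.5])
    with pytest.warns(UserWarning, match="missing"):
        roles = classify_roles(z, p)
    assert roles[1] == "other"


def test_bounds_property(rng):
    """All bounded metrics stay in [0, 1] for arbitrary partitions."""
    for _ in range(5):
        p = random_partition(rng, n=9, L=6, k=4)
        al = allegiance(p)
        ref = rng.integers(1, 3, size=9)
        for vals in (
            flexibility(p),
            promiscuity(p),
            al.values.ravel(),
            integration(al, ref),
            participation_coefficient(al, ref),
        ):
            finite = vals[np.isfinite(vals)]
            assert np.all(finite >= -1e-12) and np.all(finite <= 1 + 1e-12)


def test_planted_integrators_recovered(rng):
    """Nodes with weak, evenly distributed allegiance (the cerebellar
    signature) inside mixed reference modules classify as integrators,
    never hubs."""
    n_cortex, n_cb = 40, 8
    n = n_cortex + n_cb
    # each reference module holds 10 cortical and 2 cerebellar nodes: the
    # consensus assigns cerebellar nodes to the communities they weakly join
    ref = np.concatenate([np.repeat([1, 2, 3, 4], 10), np.tile([1, 2, 3, 4], 2)])
    hits, hub_hits = 0, 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        cb = np.arange(n_cortex, n)
        a = np.full((n, n), 0.1)
        same = ref[:, None] == ref[None, :]
        a[same] = 0.7  # cohesive in-module allegiance
        a[cb, :] = 0.35  # cerebellar: evenly spread, weak everywhere
        a[:, cb] = 0.35
        a += r.normal(0, 0.02, size=(n, n))
        a = np.clip(0.5 * (a + a.T), 0, 1)
        np.fill_diagonal(a, 1.0)
        al = AllegianceMatrix(values=a, n_layers=28)
        roles = classify_roles(
            within_module_degree(al, ref), participation_coefficient(al, ref)
        )
        hits += (roles[cb] == "integrator").mean()
        hub_hits += (roles[cb] == "hub").sum()
    assert hits / 20 >= 0.8
    assert hub_hits == 0


def test_node_metric_table_shape(small_ensemble):
    table = node_metric_table(small_ensemble, np.repeat([1, 2], 6))
    assert len(table) == 12
    assert set(table.columns) >= {
        "flexibility", "promiscuity", "integration", "recruitment",
        "participation", "within_module_degree", "role",
    }
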
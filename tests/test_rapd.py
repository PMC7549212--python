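"""Band classification, Jaccard distances, UPGMA and Newick output."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from salipheno.rapd import (BandMatrix, classify_bands, jaccard_distance,
                            jaccard_distance_matrix, upgma, write_newick)
from salipheno.synthetic import GeneratorConfig, generate_band_matrix


def small_matrix(values, pops, bands=None, primer="K01"):
    values = np.asarray(values)
    ids = [f"{p}{i}" for i, p in enumerate(pops, 1)]
    bands = bands or [f"{primer}_{j + 1}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=ids, columns=bands)
    populations = pd.Series(list(pops), index=ids)
    return BandMatrix(df, populations, {b: b.split("_")[0] for b in bands})


def test_band_present_everywhere_is_monomorphic():
    m = small_matrix([[1], [1], [1], [1]], "CCII")
    result = classify_bands(m)
    assert result.overall.iloc[0] == "monomorphic"
    assert result.n_polymorphic == 0


def test_band_varying_in_one_group_is_polymorphic():
    m = small_matrix([[1], [0], [1], [1]], "CCII")
    assert classify_bands(m).overall.iloc[0] == "polymorphic"


def test_band_fixed_differently_between_groups_is_polymorphic():
    m = small_matrix([[1], [1], [0], [0]], "CCII")
    result = classify_bands(m)
    # monomorphic within each group, but the groups are fixed differently
    assert (result.per_group.iloc[0] == "monomorphic").all()
    assert result.overall.iloc[0] == "polymorphic"


def test_default_fixture_yields_15_polymorphic_bands():
    matrix = generate_band_matrix(GeneratorConfig(seed=0))
    result = classify_bands(matrix)
    assert result.n_polymorphic == 15
    assert result.per_primer_polymorphic == {"K01": 3, "M02": 6, "OPB11": 6}
    assert matrix.values.shape == (60, 5 + 3 + 6 + 6 + 6 + 6)


def test_all_monomorphic_config_classifies_none():
    cfg = GeneratorConfig(seed=0, band_config=(("K01", 4, 0), ("M02", 3, 0)))
    result = classify_bands(generate_band_matrix(cfg))
    assert result.n_polymorphic == 0


@pytest.mark.parametrize("v1, v2, expected", [
    ([1, 1, 0], [1, 1, 0], 0.0),
    ([1, 1, 0], [1, 0, 1], 2.0 / 3.0),
    ([1, 0, 0], [0, 1, 1], 1.0),
    ([1, 1, 1, 0, 0], [1, 0, 0, 0, 0], 2.0 / 3.0),
])
def test_jaccard_hand_cases(v1, v2, expected):
    assert jaccard_distance(v1, v2) == pytest.approx(expected)


def test_jaccard_all_zero_pair_is_undefined():
    with pytest.raises(ValueError, match="all-zero"):
        jaccard_distance([0, 0], [0, 0])


binary_vec = st.lists(st.integers(0, 1), min_size=4, max_size=12)


@settings(max_examples=200, derandomize=True)
@given(binary_vec, binary_vec, binary_vec)
def test_jaccard_is_a_metric(a, b, c):
    n = max(len(a), len(b), len(c))
    a, b, c = (v + [0] * (n - len(v)) for v in (a, b, c))
    a[0] = b[0] = c[0] = 1  # avoid the undefined all-zero case
    dab, dbc, dac = (jaccard_distance(x, y)
                     for x, y in ((a, b), (b, c), (a, c)))
    assert dab == pytest.approx(jaccard_distance(b, a))
    assert jaccard_distance(a, a) == 0.0
    assert dac <= dab + dbc + 1e-12


def test_upgma_three_taxon_hand_example():
    d = pd.DataFrame([[0.0, 0.2, 0.6],
                      [0.2, 0.0, 0.6],
                      [0.6, 0.6, 0.0]],
                     index=list("ABC"), columns=list("ABC"))
    tree = upgma(d)
    assert tree.merges[0, :3].tolist() == [0, 1, 0.2]   # A,B at height 0.1
    assert tree.merges[1, 2] == pytest.approx(0.6)      # C joins at 0.3
    assert tree.root.height == pytest.approx(0.3)
    newick = write_newick(tree)
    # round-trip: leaf depths equal the root height
    from Bio import Phylo
    parsed = Phylo.read(io.StringIO(newick), "newick")
    depths = parsed.depths()
    leaf_depths = {t.name: d for t, d in depths.items() if t.name}
    assert leaf_depths == pytest.approx({"A": 0.3, "B": 0.3, "C": 0.3})


def test_upgma_equal_distances_merge_by_index():
    d = pd.DataFrame(0.4 * (1 - np.eye(4)), index=list("ABCD"),
                     columns=list("ABCD"))
    tree = upgma(d)
    assert tree.merges[0, :2].tolist() == [0, 1]  # smallest index pair first
    assert np.allclose(tree.merges[:, 2], 0.4)


def test_upgma_is_ultrametric_and_matches_average_linkage(rng):
    from scipy.cluster.hierarchy import cophenet, linkage
    from scipy.spatial.distance import squareform

    for _ in range(5):
        n = 8
        condensed = rng.uniform(0.1, 1.0, n * (n - 1) // 2)
        d = squareform(condensed)
        labels = [f"t{i}" for i in range(n)]
        dd = pd.DataFrame(d, index=labels, columns=labels)
        tree = upgma(dd)
        coph = tree.cophenetic_matrix().to_numpy()
        # ultrametric: max(d(i,k), d(j,k)) >= d(i,j) for the two largest
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-12
        expected = squareform(cophenet(linkage(condensed, "average")))
        assert np.allclose(coph, expected, atol=1e-12)


def test_upgma_cophenetic_reproduces_ultrametric_input():
    # an exactly ultrametric matrix is reproduced without distortion
    coph0 = np.array([[0.0, 0.2, 0.8, 0.8],
                      [0.2, 0.0, 0.8, 0.8],
                      [0.8, 0.8, 0.0, 0.4],
                      [0.8, 0.8, 0.4, 0.0]])
    labels = list("ABCD")
    tree = upgma(pd.DataFrame(coph0, index=labels, columns=labels))
    assert np.allclose(tree.cophenetic_matrix().to_numpy(), coph0)


def test_upgma_permutation_changes_only_leaf_order(rng):
    n = 7
    from scipy.spatial.distance import squareform
    d = squareform(rng.uniform(0.1, 1.0, n * (n - 1) // 2))
    labels = [f"t{i}" for i in range(n)]
    dd = pd.DataFrame(d, index=labels, columns=labels)
    tree = upgma(dd)
    perm = rng.permutation(n)
    dp = dd.iloc[perm, perm]
    tree_p = upgma(dp)
    c1 = tree.cophenetic_matrix().loc[labels, labels].to_numpy()
    c2 = tree_p.cophenetic_matrix().loc[labels, labels].to_numpy()
    assert np.allclose(c1, c2)


def test_newick_degenerate_cases():
    one = upgma(pd.DataFrame([[0.0]], index=["A"], columns=["A"]))
    assert write_newick(one) == "A;"
    two = upgma(pd.DataFrame([[0.0, 0.5], [0.5, 0.0]],
                             index=["A", "B"], columns=["A", "B"]))
    assert write_newick(two) == "(A:0.25,B:0.25);"


def test_private_band_populations_split_at_the_root():
    cfg = GeneratorConfig(seed=3, individuals_per_population=10,
                          band_config=(("K01", 4, 2),),
                          private_bands_per_population=4)
    matrix = generate_band_matrix(cfg)
    tree = upgma(jaccard_distance_matrix(matrix))
    left = set(tree.root.children[0].leaves())
    right = set(tree.root.children[1].leaves())
    pops = {frozenset(x[0] for x in side) for side in (left, right)}
    assert pops == {frozenset("C"), frozenset("I")}


def test_independent_clustering_confirms_population_split(rng):
    """Cross-check the root split with an independent average-linkage run."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    cfg = GeneratorConfig(seed=3, individuals_per_population=10,
                          band_config=(("K01", 4, 2),),
                          private_bands_per_population=4)
    matrix = generate_band_matrix(cfg)
    d = jaccard_distance_matrix(matrix)
    two = fcluster(linkage(squareform(d.to_numpy()), "average"), 2,
                   criterion="maxclust")
    split = pd.Series(two, index=d.index)
    by_pop = {pop: set(split[[i for i in d.index if i.startswith(pop)]])
              for pop in ("C", "I")}
    assert len(by_pop["C"]) == 1 and len(by_pop["I"]) == 1
    assert by_pop["C"] != by_pop["I"]
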
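import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import subdrift as sd
from subdrift.phylogeny import (
    Node,
    _edges,
    enumerate_rooted_topologies,
    enumerate_unrooted_topologies,
    parse_newick,
    reroot_on_edge,
    write_newick,
)


def brute_force_loglik(aln, root, params):
    """Independent oracle: sum over all internal-state assignments."""
    internals = [n for n in root.postorder() if not n.is_tip]
    Q = params.rate_matrix()
    lab = {l: i for i, l in enumerate(aln.labels)}
    P = {id(n): expm(Q * n.length) for n in root.postorder() if n is not root}
    lnL = 0.0
    for s in range(aln.n_sites):
        site_p = 0.0
        for states in itertools.product(range(4), repeat=len(internals)):
            st_map = dict(zip([id(n) for n in internals], states))
            pr = params.freqs[st_map[id(root)]]
            stack = [root]
            while stack:
                n = stack.pop()
                for c in n.children:
                    cs = aln.codes[lab[c.name], s] if c.is_tip else st_map[id(c)]
                    pr *= P[id(c)][st_map[id(n)], cs]
                    if not c.is_tip:
                        stack.append(c)
            site_p += pr
        lnL += np.log(site_p)
    return lnL


def tip_path_distances(root):
    """Pairwise tip-to-tip path lengths of a tree."""
    paths = {}

    def walk(n, acc):
        if n.is_tip:
            paths[n.name] = acc
        for c in n.children:
            walk(c, acc + [(id(c), c.length)])

    walk(root, [])
    out = {}
    for x, y in itertools.combinations(sorted(paths), 2):
        ex, ey = dict(paths[x]), dict(paths[y])
        out[(x, y)] = sum(l for i, l in paths[x] if i not in ey) + sum(
            l for i, l in paths[y] if i not in ex
        )
    return out


GTR_EXAMPLE = sd.GTRParams(
    freqs=np.array([0.3, 0.2, 0.25, 0.25]),
    rates=np.array([1.2, 2.5, 0.8, 1.1, 3.0, 1.0]),
)


# ----------------------------------------------------------------------
# likelihood
# ----------------------------------------------------------------------

def test_jc_closed_form_two_tips():
    # equal-frequency GTR with unit rates is JC69:
    # p_change = 3/4 - 3/4 exp(-4t/3), split over the 3 alternatives
    aln = sd.SiteAlignment(["a", "b"], np.array([[0], [2]]))
    for t in (0.01, 0.3, 1.5):
        tree = parse_newick(f"(a:{t / 2},b:{t / 2});")
        ln = sd.gtr_loglik(aln, sd.PhyloTree(tree), sd.GTRParams())
        p_change = 0.75 - 0.75 * np.exp(-4 * t / 3)
        assert ln == pytest.approx(np.log(0.25 * p_change / 3), abs=1e-12)


@pytest.mark.parametrize("n_tips", [3, 4, 5])
def test_loglik_matches_state_enumeration(n_tips):
    rng = np.random.default_rng(n_tips)
    labels = [f"t{i}" for i in range(n_tips)]
    topo = enumerate_unrooted_topologies(labels)[0]
    for n in topo.postorder():
        if n.length == 0 and n.children:
            n.length = float(rng.uniform(0.02, 0.3))
        elif n.is_tip:
            n.length = float(rng.uniform(0.02, 0.3))
    aln = sd.simulate_alignment(topo, GTR_EXAMPLE, 5, seed=n_tips)
    fast = sd.gtr_loglik(aln, sd.PhyloTree(topo), GTR_EXAMPLE)
    slow = brute_force_loglik(aln, topo, GTR_EXAMPLE)
    assert abs(fast - slow) < 1e-10


def test_loglik_invariant_under_rerooting():
    tree = parse_newick("((a:0.1,b:0.2):0.15,(c:0.3,d:0.05):0.08,e:0.2);")
    aln = sd.simulate_alignment(tree, GTR_EXAMPLE, 200, seed=1)
    ref = sd.gtr_loglik(aln, sd.PhyloTree(tree), GTR_EXAMPLE)
    for _, child in _edges(tree):
        rerooted = reroot_on_edge(tree, child)
        ln = sd.gtr_loglik(aln, sd.PhyloTree(rerooted, rooted=True), GTR_EXAMPLE)
        assert abs(ln - ref) < 1e-9


def test_label_mismatch_rejected():
    tree = parse_newick("(a:0.1,b:0.1);")
    aln = sd.SiteAlignment(["a", "c"], np.zeros((2, 3), dtype=np.int8))
    with pytest.raises(ValueError, match="labels"):
        sd.gtr_loglik(aln, sd.PhyloTree(tree), sd.GTRParams())


def test_gtr_rate_matrix_properties():
    q = GTR_EXAMPLE.rate_matrix()
    pi = GTR_EXAMPLE.freqs
    assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
    assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-12)  # detailed balance
    assert np.isclose(-np.dot(pi, np.diag(q)), 1.0)  # unit mean rate
    # P(t) rows are distributions
    p = GTR_EXAMPLE.transition(0.37)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)


# ----------------------------------------------------------------------
# alignments
# ----------------------------------------------------------------------

def test_genotype_to_alignment_shape(drift_table):
    table, _ = drift_table
    aln = sd.genotype_to_alignment(table)
    assert aln.codes.shape == (5, int(table.class_mask("SNP").sum()))
    assert aln.labels == table.substrains


def test_alignment_hamming_equals_snp_distances(drift_table):
    table, _ = drift_table
    aln = sd.genotype_to_alignment(table)
    m = sd.pairwise_distance(table, "SNP")
    for i, a in enumerate(aln.labels):
        for j, b in enumerate(aln.labels):
            ham = int((aln.codes[i] != aln.codes[j]).sum())
            assert ham == m.values[m.labels.index(a), m.labels.index(b)]


def test_no_snps_rejected(toy_table):
    indels = toy_table.subset(toy_table.class_mask("indel"))
    with pytest.raises(ValueError, match="no SNPs"):
        sd.genotype_to_alignment(indels)


def test_fasta_round_trip(tmp_path, drift_table):
    table, _ = drift_table
    aln = sd.genotype_to_alignment(table)
    aln.to_fasta(tmp_path / "a.fasta")
    again = sd.SiteAlignment.from_fasta(tmp_path / "a.fasta")
    assert again.labels == aln.labels
    assert np.array_equal(again.codes, aln.codes)


# ----------------------------------------------------------------------
# newick
# ----------------------------------------------------------------------

def test_newick_round_trip_and_dendropy_agreement():
    s = "((a:0.1,b:0.2):0.15,(c:0.3,d:0.05):0.08,e:0.2);"
    tree = parse_newick(s)
    assert write_newick(tree) == s.replace(" ", "")
    dendropy = pytest.importorskip("dendropy")
    dt = dendropy.Tree.get(data=write_newick(tree), schema="newick")
    ours = tip_path_distances(tree)
    pdm = dt.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in dt.taxon_namespace}
    for (x, y), v in ours.items():
        assert pdm.patristic_distance(taxa[x], taxa[y]) == pytest.approx(v)


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

def test_nj_on_published_matrix_recovers_two_clusters():
    m = sd.load_reference_matrix("SNP")
    tree = sd.nj_tree(m)
    # (ShiLt, ShiLtDvs) form a cherry apart from {BomTac, MrkTac, ShiJcl}
    cherry = None
    for n in tree.root.postorder():
        if not n.is_tip and sorted(n.tip_names()) == ["ShiLt", "ShiLtDvs"]:
            cherry = n
    assert cherry is not None


def test_nj_exact_on_additive_four_taxon_matrix():
    true = parse_newick("((a:2,b:3):1.5,(c:4,d:1):1.5);")
    d = tip_path_distances(true)
    labels = sorted(true.tip_names())
    mat = np.zeros((4, 4))
    for (x, y), v in d.items():
        i, j = labels.index(x), labels.index(y)
        mat[i, j] = mat[j, i] = v
    tree = sd.nj_tree(sd.DistanceMatrix(labels, mat))
    d2 = tip_path_distances(tree.root)
    for k, v in d.items():
        assert d2[k] == pytest.approx(v, abs=1e-9)
    # topology: (a,b) against (c,d)
    for n in tree.root.postorder():
        if not n.is_tip and len(n.tip_names()) == 2:
            assert sorted(n.tip_names()) in (["a", "b"], ["c", "d"])


def test_nj_star_matrix_total_length():
    # equidistant 4 taxa at pairwise distance 2h: every tip ends up at
    # height h from the single internal junction; total length = 4h
    h = 3.0
    labels = list("abcd")
    mat = np.full((4, 4), 2 * h)
    np.fill_diagonal(mat, 0)
    tree = sd.nj_tree(sd.DistanceMatrix(labels, mat))
    assert tree.total_length() == pytest.approx(4 * h)


def test_nj_needs_three_taxa():
    with pytest.raises(ValueError, match="at least 3"):
        sd.nj_tree(sd.DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]])))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**30))
def test_nj_exact_on_random_additive_matrices(seed):
    """NJ recovers path distances exactly from any additive matrix."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 8))
    labels = [f"t{i}" for i in range(n)]
    topos = enumerate_unrooted_topologies(labels)
    topo = topos[int(rng.integers(0, len(topos)))]
    for node in topo.postorder():
        if node is not topo:
            node.length = float(rng.uniform(0.5, 5.0))
    d = tip_path_distances(topo)
    mat = np.zeros((n, n))
    for (x, y), v in d.items():
        i, j = labels.index(x), labels.index(y)
        mat[i, j] = mat[j, i] = v
    tree = sd.nj_tree(sd.DistanceMatrix(labels, mat))
    d2 = tip_path_distances(tree.root)
    for k, v in d.items():
        assert d2[k] == pytest.approx(v, rel=1e-9)


def test_nj_agrees_with_skbio_on_random_matrix():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(0)
    n = 6
    labels = [f"t{i}" for i in range(n)]
    topos = enumerate_unrooted_topologies(labels)
    topo = topos[int(rng.integers(0, len(topos)))]
    for node in topo.postorder():
        if node is not topo:
            node.length = float(rng.uniform(0.5, 5.0))
    d = tip_path_distances(topo)
    mat = np.zeros((n, n))
    for (x, y), v in d.items():
        i, j = labels.index(x), labels.index(y)
        mat[i, j] = mat[j, i] = v
    ours = sd.nj_tree(sd.DistanceMatrix(labels, mat))
    dm = skbio.DistanceMatrix(mat, ids=labels)
    theirs = skbio.tree.nj(dm)
    ref = {
        frozenset((a, b)): theirs.find(a).distance(theirs.find(b))
        for a, b in itertools.combinations(labels, 2)
    }
    d2 = tip_path_distances(ours.root)
    for (a, b), v in d2.items():
        assert ref[frozenset((a, b))] == pytest.approx(v, rel=1e-6)


# ----------------------------------------------------------------------
# ML fitting and clock LRT
# ----------------------------------------------------------------------

def test_topology_counts():
    assert len(enumerate_unrooted_topologies(list("abcde"))) == 15
    assert len(enumerate_rooted_topologies(list("abcde"))) == 105
    with pytest.raises(ValueError, match="refusing"):
        enumerate_unrooted_topologies([f"t{i}" for i in range(9)])


def test_ml_recovers_known_topology():
    true = parse_newick("((a:0.05,b:0.05):0.04,(c:0.04,d:0.06):0.02,e:0.09);")
    aln = sd.simulate_alignment(true, sd.GTRParams(), 5000, seed=3)
    tree, params, lnl = sd.ml_fit(aln, "free")
    clades = {
        frozenset(n.tip_names())
        for n in tree.root.postorder()
        if not n.is_tip and n is not tree.root
    }
    assert frozenset("ab") in clades or frozenset("cde") in clades
    assert frozenset("cd") in clades or frozenset("abe") in clades


def test_free_lnl_at_least_clock_lnl():
    tree = parse_newick("(((a:0.04,b:0.04):0.03,e:0.07):0.01,(c:0.05,d:0.05):0.03);")
    for seed in (0, 1, 2):
        aln = sd.simulate_alignment(tree, sd.GTRParams(), 800, seed=seed)
        res = sd.clock_lrt(aln)
        assert res.lnL_free >= res.lnL_clock - 1e-6
        assert res.statistic >= -1e-6
        assert 0.0 <= res.p_value <= 1.0


def test_clock_fit_is_ultrametric_three_taxa():
    tree = parse_newick("((a:0.05,b:0.05):0.03,c:0.08);")
    aln = sd.simulate_alignment(tree, sd.GTRParams(), 500, seed=5)
    fit_tree, _, _ = sd.ml_fit(aln, "clock")
    assert fit_tree.is_ultrametric(1e-9)


def test_lrt_df_is_ntips_minus_two():
    tree = parse_newick("(((a:0.04,b:0.04):0.03,e:0.07):0.01,(c:0.05,d:0.05):0.03);")
    aln = sd.simulate_alignment(tree, sd.GTRParams(), 300, seed=8)
    res = sd.clock_lrt(aln)
    assert res.df == 3  # (2n-3) branch lengths vs (n-1) heights at n=5


def test_lrt_rejects_gross_clock_violation():
    # one tip on a 5x longer branch: high power at alpha = 0.05
    tree = parse_newick("(((a:0.04,b:0.04):0.03,e:0.35):0.01,(c:0.05,d:0.05):0.03);")
    rejected = 0
    for seed in range(8):
        aln = sd.simulate_alignment(tree, sd.GTRParams(), 5000, seed=seed)
        rejected += sd.clock_lrt(aln).p_value < 0.05
    assert rejected >= 7


def test_ml_fit_taxa_guard():
    aln = sd.SiteAlignment([f"t{i}" for i in range(9)], np.zeros((9, 4), dtype=np.int8))
    with pytest.raises(ValueError, match="3..8"):
        sd.ml_fit(aln)
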
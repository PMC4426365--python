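"""Small-taxon phylogenetics: NJ, GTR maximum likelihood, clock LRT.

For a handful of fully inbred lines the phylogenetic problem is tiny: a
five-tip tree has 15 unrooted topologies, so maximum likelihood can simply
enumerate them, optimizing branch lengths (and GTR exchangeabilities) for
each, instead of heuristic tree search.  The molecular-clock hypothesis —
that branch lengths are proportional to elapsed time — is tested by a
likelihood-ratio test between the unconstrained fit (2n-3 free branch
lengths) and the clock-constrained fit (n-1 free node heights on a rooted,
ultrametric tree), with 2*Delta(lnL) referred to a chi-square with n-2
degrees of freedom.

The substitution model is the general time-reversible (GTR) model: four
base frequencies (estimated empirically) and six exchangeabilities (the
last fixed at 1 for identifiability).  Likelihoods use Felsenstein pruning
with transition matrices exp(Qt) from the symmetric eigendecomposition of
the rate matrix; site patterns are compressed before evaluation.

Alignments here are concatenations of per-site homozygous calls (one
column per SNP), which is ascertainment-biased toward variable sites; the
test is computed on them as-is, exactly as one would run it on a
fixed-difference panel.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import cached_property
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from .divergence import DistanceMatrix
from .genotypes import GenotypeTable

__all__ = [
    "Node",
    "PhyloTree",
    "GTRParams",
    "LRTResult",
    "SiteAlignment",
    "parse_newick",
    "write_newick",
    "genotype_to_alignment",
    "nj_tree",
    "gtr_loglik",
    "ml_fit",
    "clock_lrt",
    "simulate_alignment",
    "enumerate_unrooted_topologies",
    "enumerate_rooted_topologies",
]

BASES = ("A", "C", "G", "T")
_CODE = {b: i for i, b in enumerate(BASES)}

MAX_TAXA = 8  # combinatorial guard for exhaustive topology enumeration


# ======================================================================
# trees
# ======================================================================

class Node:
    """A tree node; ``length`` is the branch above it (root: ignored)."""

    __slots__ = ("name", "length", "children")

    def __init__(self, name: str | None = None, length: float = 0.0, children=None):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = list(children) if children else []

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def copy(self) -> "Node":
        return Node(self.name, self.length, [c.copy() for c in self.children])

    def __repr__(self) -> str:
        return f"Node({write_newick(self)})"


def write_newick(root: Node, lengths: bool = True, fmt: str = "%.10g") -> str:
    def _w(n: Node) -> str:
        if n.is_tip:
            s = n.name or ""
        else:
            s = "(" + ",".join(_w(c) for c in n.children) + ")" + (n.name or "")
        return s

    def _wl(n: Node, top: bool) -> str:
        if n.is_tip:
            s = n.name or ""
        else:
            s = "(" + ",".join(_wl(c, False) for c in n.children) + ")" + (n.name or "")
        if not top:
            s += ":" + (fmt % n.length)
        return s

    return (_wl(root, True) if lengths else _w(root)) + ";"


def parse_newick(s: str) -> Node:
    """Parse a newick string into a :class:`Node` tree."""
    s = s.strip().rstrip(";")
    pos = 0

    def _name() -> str:
        nonlocal pos
        m = re.match(r"[^(),:;\[\]]*", s[pos:])
        pos += m.end()
        return m.group(0).strip()

    def _length() -> float:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            m = re.match(r":\s*([0-9.eE+\-]+)", s[pos:])
            if m is None:
                raise ValueError(f"bad branch length at position {pos}")
            pos += m.end()
            return float(m.group(1))
        return 0.0

    def _subtree() -> Node:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            children = [_subtree()]
            while s[pos] == ",":
                pos += 1
                children.append(_subtree())
            if s[pos] != ")":
                raise ValueError(f"expected ')' at position {pos}")
            pos += 1
            node = Node(name=_name() or None, children=children)
        else:
            name = _name()
            if not name:
                raise ValueError(f"expected a taxon name at position {pos}")
            node = Node(name=name)
        node.length = _length()
        return node

    root = _subtree()
    if pos != len(s):
        raise ValueError(f"trailing characters at position {pos}")
    return root


@dataclass
class PhyloTree:
    """A phylogeny: topology plus branch lengths (substitutions/site)."""

    root: Node
    rooted: bool = False

    def __post_init__(self) -> None:
        for n in self.root.postorder():
            if n is not self.root and n.length < 0:
                raise ValueError("branch lengths must be >= 0")

    def tip_names(self) -> list[str]:
        return self.root.tip_names()

    def newick(self, lengths: bool = True) -> str:
        return write_newick(self.root, lengths=lengths)

    def root_to_tip_depths(self) -> dict[str, float]:
        out: dict[str, float] = {}

        def _w(n: Node, d: float) -> None:
            if n.is_tip:
                out[n.name] = d
            for c in n.children:
                _w(c, d + c.length)

        _w(self.root, 0.0)
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.root_to_tip_depths().values())
        return max(depths) - min(depths) <= tol

    def total_length(self) -> float:
        return sum(n.length for n in self.root.postorder() if n is not self.root)


def _edges(root: Node) -> list[tuple[Node, Node]]:
    out = []

    def _w(n: Node) -> None:
        for c in n.children:
            out.append((n, c))
            _w(c)

    _w(root)
    return out


def reroot_on_edge(root: Node, target: Node, split: float = 0.5) -> Node:
    """Reroot an (unrooted-style) tree on the edge above ``target``.

    Returns a new rooted binary tree; the target edge's length is divided
    ``split : 1 - split`` between the two root children.  Path lengths
    between tips are preserved, so for a reversible model the likelihood is
    unchanged (the pulley principle).
    """
    parent_of: dict[int, Node] = {}
    nodes: dict[int, Node] = {}

    def _index(n: Node) -> None:
        nodes[id(n)] = n
        for c in n.children:
            parent_of[id(c)] = n
            _index(c)

    _index(root)
    if id(target) not in parent_of:
        raise ValueError("target must be a non-root node of the tree")

    def _flip(n: Node, exclude: Node) -> Node:
        """Rebuild ``n`` as seen from ``exclude``: remaining children plus
        the flipped parent (edge lengths move with the node they hang from)."""
        kids = [c.copy() for c in n.children if c is not exclude]
        p = parent_of.get(id(n))
        if p is not None:
            up = _flip(p, n)
            up.length = n.length
            kids.append(up)
        node = Node(name=n.name, children=kids)
        return node

    t = target.copy()
    other = _flip(parent_of[id(target)], target)
    t.length = target.length * split
    other.length = target.length * (1.0 - split)
    return Node(children=[t, other])


# ======================================================================
# GTR model
# ======================================================================

RATE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")


@dataclass
class GTRParams:
    """GTR substitution model: base frequencies + exchangeabilities.

    ``rates`` follow the order AC, AG, AT, CG, CT, GT with GT fixed at 1
    for identifiability.  The rate matrix is scaled to one expected
    substitution per site per unit branch length.
    """

    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    rates: np.ndarray = field(default_factory=lambda: np.ones(6))

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.freqs.shape != (4,) or self.rates.shape != (6,):
            raise ValueError("freqs must have length 4 and rates length 6")
        if np.any(self.freqs <= 0) or abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("freqs must be positive and sum to 1")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be positive")

    def rate_matrix(self) -> np.ndarray:
        """Q with detailed balance pi_i Q_ij = pi_j Q_ji, rows sum 0, mean rate 1."""
        s = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, combinations(range(4), 2)):
            s[i, j] = s[j, i] = r
        q = s * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(self.freqs, np.diag(q))
        return q / mu

    @cached_property
    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        q = self.rate_matrix()
        d = np.sqrt(self.freqs)
        sym = (q * d[:, None]) / d[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        left = u.T * d[None, :]        # U^T D^{1/2}
        right = u / d[:, None]         # D^{-1/2} U
        return lam, right, left

    def transition(self, t: float | np.ndarray) -> np.ndarray:
        """P(t) = exp(Qt); vectorized over an array of branch lengths."""
        lam, right, left = self._eigen
        t = np.asarray(t, dtype=float)
        ex = np.exp(np.multiply.outer(t, lam))  # (..., 4)
        p = np.einsum("ik,...k,kj->...ij", right, ex, left)
        return np.clip(p, 0.0, None)


def empirical_freqs(aln: "SiteAlignment", pseudocount: float = 1.0) -> np.ndarray:
    counts = np.bincount(aln.codes.ravel(), minlength=4).astype(float) + pseudocount
    return counts / counts.sum()


# ======================================================================
# alignments
# ======================================================================

class SiteAlignment:
    """Aligned A/C/G/T columns built from per-substrain homozygous calls."""

    def __init__(self, labels: list[str], codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2 or codes.shape[0] != len(labels):
            raise ValueError("codes must be (n_labels, n_sites)")
        if codes.size and (codes.min() < 0 or codes.max() > 3):
            raise ValueError("codes must be in 0..3")
        self.labels = list(labels)
        self.codes = codes

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @cached_property
    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique site patterns and their multiplicities."""
        pats, counts = np.unique(self.codes, axis=1, return_counts=True)
        return pats, counts.astype(float)

    def sequences(self) -> dict[str, str]:
        return {
            lab: "".join(BASES[c] for c in row)
            for lab, row in zip(self.labels, self.codes)
        }

    def to_fasta(self, path: str | Path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(Seq(seq), id=lab, description="")
            for lab, seq in self.sequences().items()
        ]
        seqio_write(recs, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "SiteAlignment":
        from Bio.SeqIO import parse as seqio_parse

        labels, rows = [], []
        for rec in seqio_parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append([_CODE[b] for b in str(rec.seq).upper()])
        return cls(labels, np.array(rows, dtype=np.int8))


def genotype_to_alignment(table: GenotypeTable) -> SiteAlignment:
    """One alignment column per SNP (indels excluded)."""
    mask = table.class_mask("SNP")
    if not mask.any():
        raise ValueError("genotype table contains no SNPs")
    sub = table.subset(mask)
    codes = np.empty((sub.n_substrains, len(sub)), dtype=np.int8)
    for i in range(len(sub)):
        ref = _CODE[sub.variants.iloc[i]["ref"]]
        alt = _CODE[sub.variants.iloc[i]["alt"]]
        codes[:, i] = np.where(sub.calls[i], alt, ref)
    return SiteAlignment(sub.substrains, codes)


# ======================================================================
# likelihood
# ======================================================================

def _pruning_loglik(
    root: Node,
    patterns: np.ndarray,
    weights: np.ndarray,
    label_row: dict[str, int],
    params: GTRParams,
) -> float:
    """Felsenstein pruning over compressed site patterns."""

    def _partial(n: Node) -> np.ndarray:
        prod = None
        for c in n.children:
            p = params.transition(max(c.length, 0.0))
            if c.is_tip:
                msg = p[:, patterns[label_row[c.name]]].T  # (n_pat, 4)
            else:
                msg = _partial(c) @ p.T
            prod = msg if prod is None else prod * msg
        return prod

    part = _partial(root)
    site = part @ params.freqs
    return float(np.dot(weights, np.log(np.maximum(site, 1e-300))))


def gtr_loglik(aln: SiteAlignment, tree: PhyloTree | Node, params: GTRParams) -> float:
    """Log-likelihood of the alignment on the tree under GTR."""
    root = tree.root if isinstance(tree, PhyloTree) else tree
    if sorted(root.tip_names()) != sorted(aln.labels):
        raise ValueError("tree tips and alignment labels do not match")
    pats, w = aln.patterns
    label_row = {lab: i for i, lab in enumerate(aln.labels)}
    return _pruning_loglik(root, pats, w, label_row, params)


def simulate_alignment(
    tree: PhyloTree | Node,
    params: GTRParams,
    n_sites: int,
    seed: int | np.random.Generator = 0,
) -> SiteAlignment:
    """Evolve ``n_sites`` independent sites along a rooted tree under GTR."""
    root = tree.root if isinstance(tree, PhyloTree) else tree
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = root.tip_names()
    out = {}

    def _evolve(n: Node, states: np.ndarray) -> None:
        for c in n.children:
            p = params.transition(max(c.length, 0.0))
            cum = np.cumsum(p[states], axis=1)
            u = rng.random(len(states))
            child_states = (u[:, None] > cum).sum(axis=1).astype(np.int8)
            if c.is_tip:
                out[c.name] = child_states
            else:
                _evolve(c, child_states)

    root_states = rng.choice(4, size=n_sites, p=params.freqs).astype(np.int8)
    _evolve(root, root_states)
    return SiteAlignment(labels, np.array([out[lab] for lab in labels]))


# ======================================================================
# neighbor joining
# ======================================================================

def nj_tree(m: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree from a distance matrix.

    Ties in the Q criterion are broken by lexicographic pair order (pairs
    ordered by the smallest tip label in each cluster).  Negative branch
    lengths are clamped to zero with the deficit shifted to the sister
    edge, preserving the joined pair's distance.
    """
    labels = list(m.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {(a, b): float(m[(a, b)]) for a in labels for b in labels if a != b}
    nodes: dict[str, Node] = {lab: Node(name=lab) for lab in labels}
    rep: dict[str, str] = {lab: lab for lab in labels}  # lexicographic representative
    active = list(labels)

    def dist(a: str, b: str) -> float:
        return d[(a, b)] if a != b else 0.0

    while len(active) > 3:
        r = len(active)
        rsum = {a: sum(dist(a, b) for b in active) for a in active}
        best, best_pair = None, None
        for a, b in combinations(active, 2):
            q = (r - 2) * dist(a, b) - rsum[a] - rsum[b]
            key = tuple(sorted((rep[a], rep[b])))
            if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                best, best_pair = (q, key), (a, b)
        a, b = best_pair
        la = 0.5 * dist(a, b) + (rsum[a] - rsum[b]) / (2.0 * (r - 2))
        lb = dist(a, b) - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        u = f"__u{len(nodes)}"
        na, nb = nodes[a], nodes[b]
        na.length, nb.length = la, lb
        nodes[u] = Node(children=[na, nb])
        rep[u] = min(rep[a], rep[b])
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
            d[(u, c)] = d[(c, u)] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = active
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    for lab, ln in zip((a, b, c), (la, lb, lc)):
        nodes[lab].length = max(ln, 0.0)
    return PhyloTree(Node(children=[nodes[a], nodes[b], nodes[c]]), rooted=False)


# ======================================================================
# topology enumeration
# ======================================================================

def enumerate_unrooted_topologies(labels: list[str]) -> list[Node]:
    """All unrooted topologies ((2n-5)!! of them) as trifurcating-root trees."""
    labels = sorted(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if n > MAX_TAXA:
        raise ValueError(f"refusing exhaustive enumeration for >{MAX_TAXA} taxa")
    trees = [Node(children=[Node(name=labels[0]), Node(name=labels[1]), Node(name=labels[2])])]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            for k in range(len(_edges(t))):
                t2 = t.copy()
                parent, child = _edges(t2)[k]
                parent.children.remove(child)
                parent.children.append(Node(children=[child, Node(name=lab)]))
                nxt.append(t2)
        trees = nxt
    return trees


def enumerate_rooted_topologies(labels: list[str]) -> list[Node]:
    """All rooted binary topologies ((2n-3)!! of them)."""
    labels = sorted(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n > MAX_TAXA:
        raise ValueError(f"refusing exhaustive enumeration for >{MAX_TAXA} taxa")
    trees = [Node(children=[Node(name=labels[0]), Node(name=labels[1])])]
    for lab in labels[2:]:
        nxt = []
        for t in trees:
            for k in range(len(_edges(t))):
                t2 = t.copy()
                parent, child = _edges(t2)[k]
                parent.children.remove(child)
                parent.children.append(Node(children=[child, Node(name=lab)]))
                nxt.append(t2)
            t2 = Node(children=[t.copy(), Node(name=lab)])  # new root above the old one
            nxt.append(t2)
        trees = nxt
    return trees


def _rootings(unrooted: Node) -> list[Node]:
    """All rooted binary versions of an unrooted (trifurcating-root) tree."""
    out = []
    for _, child in _edges(unrooted):
        out.append(reroot_on_edge(unrooted, child))
    return out


# ======================================================================
# maximum likelihood
# ======================================================================

_BL_BOUNDS = (1e-9, 10.0)
_OPT_TOL = 1e-8
_MAX_ITER = 500


def _optimize_branch_lengths(
    topo: Node,
    aln: SiteAlignment,
    params: GTRParams,
    optimize_rates: bool = False,
    x0_bl: float = 0.05,
) -> tuple[Node, GTRParams, float]:
    """Maximize lnL over branch lengths (and optionally exchangeabilities)."""
    tree = topo.copy()
    branches = [c for _, c in _edges(tree)]
    pats, w = aln.patterns
    label_row = {lab: i for i, lab in enumerate(aln.labels)}
    nb = len(branches)

    def _set(x: np.ndarray) -> GTRParams:
        for node, t in zip(branches, x[:nb]):
            node.length = t
        if optimize_rates:
            rates = np.append(np.exp(x[nb:]), 1.0)
            return GTRParams(freqs=params.freqs, rates=rates)
        return params

    def negll(x: np.ndarray) -> float:
        p = _set(x)
        return -_pruning_loglik(tree, pats, w, label_row, p)

    x0 = np.full(nb, x0_bl)
    bounds = [_BL_BOUNDS] * nb
    if optimize_rates:
        x0 = np.concatenate([x0, np.log(params.rates[:5])])
        bounds += [(-7.0, 7.0)] * 5
    res = optimize.minimize(
        negll, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": _OPT_TOL, "maxiter": _MAX_ITER},
    )
    fitted = _set(res.x)
    return tree, fitted, -float(res.fun)


def _optimize_clock_heights(
    topo: Node,
    aln: SiteAlignment,
    params: GTRParams,
    x0_height: float = 0.05,
) -> tuple[Node, float]:
    """Maximize lnL over node heights of a rooted topology (ultrametric)."""
    tree = topo.copy()
    internals = [n for n in tree.postorder() if not n.is_tip and n is not tree]
    # preorder (parents first) for nested height computation
    preorder: list[Node] = []

    def _pre(n: Node) -> None:
        if not n.is_tip and n is not tree:
            preorder.append(n)
        for c in n.children:
            _pre(c)

    _pre(tree)
    pats, w = aln.patterns
    label_row = {lab: i for i, lab in enumerate(aln.labels)}

    def _set(x: np.ndarray) -> None:
        heights = {id(tree): x[0]}
        for node, f in zip(preorder, x[1:]):
            parent_h = heights[_parent_height_key(node)]
            heights[id(node)] = f * parent_h

        def _apply(n: Node, h: float) -> None:
            for c in n.children:
                ch = 0.0 if c.is_tip else heights[id(c)]
                c.length = max(h - ch, 0.0)
                _apply(c, ch)

        _apply(tree, x[0])

    parent_map = {id(c): p for p, c in _edges(tree)}

    def _parent_height_key(node: Node) -> int:
        return id(parent_map[id(node)])

    def negll(x: np.ndarray) -> float:
        _set(x)
        return -_pruning_loglik(tree, pats, w, label_row, params)

    x0 = np.array([x0_height] + [0.5] * len(preorder))
    bounds = [(1e-8, 10.0)] + [(1e-6, 1.0 - 1e-6)] * len(preorder)
    res = optimize.minimize(
        negll, x0, method="L-BFGS-B", bounds=bounds,
        options={"ftol": _OPT_TOL, "maxiter": _MAX_ITER},
    )
    _set(res.x)
    return tree, -float(res.fun)


def ml_fit(
    aln: SiteAlignment,
    constraint: str = "free",
    params: GTRParams | None = None,
    optimize_rates: bool = True,
    topologies: list[Node] | None = None,
) -> tuple[PhyloTree, GTRParams, float]:
    """Exhaustive-enumeration ML fit under GTR.

    ``constraint="free"`` enumerates unrooted topologies and optimizes the
    2n-3 branch lengths per topology; ``constraint="clock"`` enumerates
    rooted topologies and optimizes the n-1 nested node heights, returning
    an ultrametric tree.  Topologies are ranked with exchangeabilities held
    at their initial values; when ``optimize_rates`` is on (and no fixed
    ``params`` given), the two best-ranked topologies are then refitted
    with exchangeabilities free and the better one returned.

    Base frequencies are estimated empirically from the alignment unless
    ``params`` is given, in which case the model is held fixed throughout.
    """
    n = len(aln.labels)
    if not 3 <= n <= MAX_TAXA:
        raise ValueError(f"ml_fit supports 3..{MAX_TAXA} taxa, got {n}")
    fixed_model = params is not None
    if params is None:
        params = GTRParams(freqs=empirical_freqs(aln))
    if constraint not in ("free", "clock"):
        raise ValueError(f"unknown constraint {constraint!r}")

    if topologies is None:
        if constraint == "free":
            topologies = enumerate_unrooted_topologies(aln.labels)
        elif n <= 6:
            topologies = enumerate_rooted_topologies(aln.labels)
        else:
            # full rooted enumeration is combinatorially heavy; root the
            # free ML topology instead
            free_tree, _, _ = ml_fit(aln, "free", params=params, optimize_rates=False)
            topologies = _rootings(free_tree.root)

    fits = []
    for topo in topologies:
        if constraint == "free":
            tree, p, lnl = _optimize_branch_lengths(topo, aln, params, optimize_rates=False)
        else:
            tree, lnl = _optimize_clock_heights(topo, aln, params)
            p = params
        fits.append((lnl, tree, p))
    fits.sort(key=lambda f: f[0], reverse=True)

    if optimize_rates and not fixed_model:
        refined = []
        for lnl, tree, p in fits[:2]:
            if constraint == "free":
                t2, p2, l2 = _optimize_branch_lengths(tree, aln, params, optimize_rates=True)
            else:
                p2 = _fit_rates_on_tree(tree, aln, params)
                t2, l2 = _optimize_clock_heights(tree, aln, p2)
            refined.append((l2, t2, p2))
        refined.sort(key=lambda f: f[0], reverse=True)
        fits = refined
    lnl, tree, p = fits[0]
    return PhyloTree(tree, rooted=(constraint == "clock")), p, lnl


def _fit_rates_on_tree(tree: Node, aln: SiteAlignment, params: GTRParams) -> GTRParams:
    """Optimize exchangeabilities on a fixed tree (branch lengths fixed)."""
    pats, w = aln.patterns
    label_row = {lab: i for i, lab in enumerate(aln.labels)}

    def negll(logr: np.ndarray) -> float:
        p = GTRParams(freqs=params.freqs, rates=np.append(np.exp(logr), 1.0))
        return -_pruning_loglik(tree, pats, w, label_row, p)

    res = optimize.minimize(
        negll, np.log(params.rates[:5]), method="L-BFGS-B",
        bounds=[(-7.0, 7.0)] * 5, options={"ftol": _OPT_TOL, "maxiter": _MAX_ITER},
    )
    return GTRParams(freqs=params.freqs, rates=np.append(np.exp(res.x), 1.0))


# ======================================================================
# clock LRT
# ======================================================================

@dataclass
class LRTResult:
    """Likelihood-ratio test of the molecular clock."""

    lnL_free: float
    lnL_clock: float
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < -1e-6:
            raise ValueError(
                f"negative LRT statistic ({self.statistic}): optimizer failure"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "lnL_free": self.lnL_free,
                    "lnL_clock": self.lnL_clock,
                    "statistic": self.statistic,
                    "df": self.df,
                    "p_value": self.p_value,
                },
                indent=2,
                sort_keys=True,
            )
        )


def clock_lrt(aln: SiteAlignment, params: GTRParams | None = None) -> LRTResult:
    """Test the molecular clock by likelihood ratio.

    Fits the unconstrained model (2n-3 branch lengths, exhaustive topology
    enumeration), then the clock model over all rootings of the free ML
    topology with the substitution model shared between the two fits.  The
    statistic 2*(lnL_free - lnL_clock) is referred to chi-square with
    n - 2 degrees of freedom ((2n-3) branch parameters vs (n-1) heights).
    """
    n = len(aln.labels)
    free_tree, fitted, lnl_free = ml_fit(
        aln, "free", params=params, optimize_rates=params is None
    )
    clock_tree, _, lnl_clock = ml_fit(
        aln, "clock", params=fitted, topologies=_rootings(free_tree.root)
    )
    if params is None:
        # let the null model optimize its own exchangeabilities too, so both
        # fits maximize over the same substitution-model parameters
        p2 = _fit_rates_on_tree(clock_tree.root, aln, fitted)
        _, lnl_refit = _optimize_clock_heights(clock_tree.root, aln, p2)
        lnl_clock = max(lnl_clock, lnl_refit)
    stat = 2.0 * (lnl_free - lnl_clock)
    df = n - 2
    return LRTResult(
        lnL_free=lnl_free,
        lnL_clock=lnl_clock,
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(max(stat, 0.0), df)),
    )
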
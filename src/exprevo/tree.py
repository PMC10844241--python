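"""Species-tree data model and trait-evolution covariance kernels.

The tree is rooted with branch lengths in millions of years (My).  Two
Gaussian kernels over the tips are provided:

* Brownian motion (BM): ``Cov(i, j) = sigma2 * t_ij`` where ``t_ij`` is the
  shared root-to-MRCA path length — the neutral-drift model.
* Ornstein-Uhlenbeck (OU): mean reversion toward an optimum with strength
  ``alpha`` (1/My).  The stationary form has tip variance
  ``sigma2 / (2 alpha)`` and covariance decaying as ``exp(-alpha * d_ij)``
  in the patristic distance ``d_ij``.  A fixed-root variant
  (``stationary=False``) conditions on the root state and degenerates
  exactly to BM as ``alpha -> 0``.

Within-species replicate noise is modelled as iid Gaussian with variance
``sigma2_e`` added on the diagonal of the replicate-level covariance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "SpeciesTree",
    "OUParams",
    "Regime",
    "read_tree",
    "write_tree",
    "bm_covariance",
    "ou_covariance",
    "replicate_covariance",
    "regime_from_shifts",
    "oum_design_weights",
    "drosophila_tree",
    "DROSOPHILA_NEWICK",
]

#: Six-species Drosophila melanogaster-group phylogeny with divergence dates
#: in My (sim/sec split 0.25 My, root 15 My).
DROSOPHILA_NEWICK = (
    "(((Dmel:3,(Dsim:0.25,Dsec:0.25):2.75):7,(Dsan:6,Dere:6):4):5,Dsuz:15);"
)


class SpeciesTree:
    """Rooted phylogeny with branch lengths.

    Nodes are integer ids ``0..n_nodes-1``; tips come first, in the order of
    ``tip_names``.  An *edge* is identified by its child node id.  All
    operations index species by name, so any tip order is accepted.
    """

    def __init__(
        self,
        tip_names: list[str],
        parent: np.ndarray,
        lengths: np.ndarray,
        root: int,
    ):
        self.tip_names = list(tip_names)
        if len(set(self.tip_names)) != len(self.tip_names):
            raise ValueError("tip names must be unique")
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.root = int(root)
        self.n_taxa = len(tip_names)
        self.n_nodes = len(parent)
        bad = [
            i
            for i in range(self.n_nodes)
            if i != self.root and not (self.lengths[i] > 0)
        ]
        if bad:
            raise ValueError(f"non-positive or missing branch lengths at nodes {bad}")
        self._index = {name: i for i, name in enumerate(tip_names)}
        self._children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if i != self.root:
                self._children[self.parent[i]].append(i)
        # edges = all non-root nodes (edge above that node)
        self.edges: list[int] = [i for i in range(self.n_nodes) if i != self.root]
        self._clades: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node < self.n_taxa:
                self._clades[node] = frozenset([self.tip_names[node]])
            else:
                s: frozenset[str] = frozenset()
                for c in self._children[node]:
                    s |= self._clades[c]
                self._clades[node] = s

    # ---- structure -----------------------------------------------------
    def children(self, node: int) -> list[int]:
        return self._children[node]

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self._children[node])
        return order[::-1]

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def clade(self, edge: int) -> frozenset[str]:
        """Tip names descending from the child end of ``edge``."""
        return self._clades[edge]

    def edge_label(self, edge: int) -> str:
        return "+".join(sorted(self.clade(edge)))

    def edge_by_label(self, label: str) -> int:
        want = frozenset(label.split("+"))
        for e in self.edges:
            if self._clades[e] == want:
                return e
        raise KeyError(f"no edge with clade {label!r}")

    def tip_index(self, names) -> np.ndarray:
        try:
            return np.array([self._index[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"species {exc} not in tree") from None

    def root_path(self, node: int) -> list[int]:
        """Edges (child-node ids) from ``node`` up to the root, tipward first."""
        path = []
        while node != self.root:
            path.append(node)
            node = self.parent[node]
        return path

    # ---- metrics -------------------------------------------------------
    def node_depths(self) -> np.ndarray:
        depth = np.zeros(self.n_nodes)
        for node in self.preorder():
            if node != self.root:
                depth[node] = depth[self.parent[node]] + self.lengths[node]
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[: self.n_taxa]

    def shared_time_matrix(self) -> np.ndarray:
        """(i, j) -> root-to-MRCA path length; diagonal = tip depths."""
        depth = self.node_depths()
        n = self.n_taxa
        out = np.zeros((n, n))
        paths = [set(self.root_path(i) + [self.root]) for i in range(n)]
        # MRCA = deepest node common to both root paths
        node_sets = [
            {self.parent[e] for e in self.root_path(i)} | {i} for i in range(n)
        ]
        for i in range(n):
            for j in range(n):
                common = node_sets[i] & node_sets[j]
                out[i, j] = max(depth[k] for k in common)
        return out

    def patristic_matrix(self) -> np.ndarray:
        depth = self.tip_depths()
        shared = self.shared_time_matrix()
        return depth[:, None] + depth[None, :] - 2.0 * shared

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return bool(np.ptp(d) <= rel_tol * d.max())

    # ---- io ------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "SpeciesTree":
        dnodes = list(dtree.preorder_node_iter())
        tips = [n for n in dnodes if n.is_leaf()]
        internals = [n for n in dnodes if not n.is_leaf()]
        tip_names = [t.taxon.label for t in tips]
        ids = {id(n): k for k, n in enumerate(tips)}
        for k, n in enumerate(internals):
            ids[id(n)] = len(tips) + k
        n_nodes = len(dnodes)
        parent = np.full(n_nodes, -1, dtype=int)
        lengths = np.zeros(n_nodes)
        root = ids[id(dtree.seed_node)]
        for n in dnodes:
            i = ids[id(n)]
            if n.parent_node is not None:
                parent[i] = ids[id(n.parent_node)]
                if n.edge.length is None:
                    raise ValueError(
                        f"missing branch length above node {n.taxon.label if n.taxon else i}"
                    )
                lengths[i] = float(n.edge.length)
        return cls(tip_names, parent, lengths, root)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_names)
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = {self.root: dtree.seed_node}
        for node in self.preorder():
            if node == self.root:
                continue
            parent = dnodes[self.parent[node]]
            child = parent.new_child(edge_length=float(self.lengths[node]))
            dnodes[node] = child
            if node < self.n_taxa:
                child.taxon = taxa.get_taxon(self.tip_names[node])
        return dtree

    def to_newick(self) -> str:
        return (
            self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"SpeciesTree(n_taxa={self.n_taxa}, tips={self.tip_names})"


def read_tree(newick_text: str) -> SpeciesTree:
    """Parse a rooted newick string with branch lengths."""
    try:
        dtree = dendropy.Tree.get(
            data=newick_text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    return SpeciesTree.from_dendropy(dtree)


def write_tree(tree: SpeciesTree) -> str:
    return tree.to_newick()


def drosophila_tree() -> SpeciesTree:
    """The packaged six-species calibrated phylogeny (depth 15 My)."""
    return read_tree(DROSOPHILA_NEWICK)


@dataclass
class OUParams:
    """Parameters of the OU trait model on the log2(TPM+1) scale.

    alpha: selection strength (1/My, >= 0; 0 degenerates to BM).
    sigma2: drift variance rate (expr^2/My, > 0).
    sigma2_e: within-species replicate variance (expr^2, >= 0).
    """

    alpha: float
    sigma2: float
    sigma2_e: float = 0.0

    def __post_init__(self):
        if not np.isfinite([self.alpha, self.sigma2, self.sigma2_e]).all():
            raise ValueError("OU parameters must be finite")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.sigma2_e < 0:
            raise ValueError("sigma2_e must be >= 0")

    @property
    def stationary_var(self) -> float:
        if self.alpha == 0:
            raise ValueError("stationary variance undefined at alpha = 0")
        return self.sigma2 / (2.0 * self.alpha)


@dataclass
class Regime:
    """Assignment of expression optima to tree edges.

    ``optimum_index[edge]`` gives the optimum (0 = root optimum) governing
    that edge; ``shift_edges`` are the edges where the index differs from the
    parent edge.  ``optima`` (theta values, log2(TPM+1) units) may be left
    None until fitted.
    """

    optimum_index: dict[int, int]
    shift_edges: frozenset[int]
    optima: np.ndarray | None = None

    @property
    def n_optima(self) -> int:
        return len(self.shift_edges) + 1

    def validate(self, tree: SpeciesTree) -> None:
        if set(self.optimum_index) != set(tree.edges):
            raise ValueError("regime must cover exactly the tree's edges")
        idx = set(self.optimum_index.values())
        # the root carries optimum 0; if both root-child edges shift, no edge
        # carries index 0 but the optimum still exists at the root
        if not idx <= set(range(self.n_optima)) or len(idx | {0}) != self.n_optima:
            raise ValueError(
                "number of distinct optima must equal number of shift edges + 1"
            )
        for e in tree.edges:
            par = tree.parent[e]
            par_idx = 0 if par == tree.root else self.optimum_index[par]
            changed = self.optimum_index[e] != par_idx
            if changed != (e in self.shift_edges):
                raise ValueError(f"shift_edges inconsistent at edge {e}")


def regime_from_shifts(tree: SpeciesTree, shift_edges) -> Regime:
    """Build the nearest-ancestral-shift regime for a set of shift edges.

    Each shift edge starts a new optimum governing itself and all descendant
    edges down to the next shift; everything else keeps the root optimum 0.
    """
    shift_edges = sorted(set(shift_edges))
    if any(e not in tree.edges for e in shift_edges):
        raise ValueError("shift edge not in tree")
    number = {e: k + 1 for k, e in enumerate(shift_edges)}
    optimum_index: dict[int, int] = {}
    for node in tree.preorder():
        if node == tree.root:
            continue
        if node in number:
            optimum_index[node] = number[node]
        else:
            par = tree.parent[node]
            optimum_index[node] = 0 if par == tree.root else optimum_index[par]
    return Regime(optimum_index=optimum_index, shift_edges=frozenset(shift_edges))


# ---- covariance kernels -------------------------------------------------


def bm_covariance(tree: SpeciesTree, sigma2: float) -> np.ndarray:
    """Brownian-motion tip covariance: sigma2 x shared root-to-MRCA time."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    return sigma2 * tree.shared_time_matrix()


def ou_covariance(
    tree: SpeciesTree, params: OUParams, stationary: bool = True
) -> np.ndarray:
    """OU tip covariance.

    Stationary (default): the root state is drawn from the stationary
    distribution, so ``Cov(i,j) = sigma2/(2 alpha) * exp(-alpha d_ij)``.
    Fixed-root: conditioning on the root state gives
    ``sigma2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha t_ij))``,
    which converges to the BM kernel as alpha -> 0.
    """
    if params.alpha <= 0:
        raise ValueError("alpha must be > 0 for the OU kernel; use bm_covariance")
    d = tree.patristic_matrix()
    v = params.stationary_var
    cov = v * np.exp(-params.alpha * d)
    if not stationary:
        t = tree.shared_time_matrix()
        cov = cov * (1.0 - np.exp(-2.0 * params.alpha * t))
    return cov


def replicate_covariance(
    species_cov: np.ndarray, species_of_sample: np.ndarray, sigma2_e: float
) -> np.ndarray:
    """Expand a species-level covariance to replicate samples.

    ``species_of_sample[k]`` is the species (row of ``species_cov``) of
    sample k.  Replicate noise adds ``sigma2_e`` to the diagonal only.
    """
    if sigma2_e < 0:
        raise ValueError("sigma2_e must be >= 0")
    idx = np.asarray(species_of_sample, dtype=int)
    cov = species_cov[np.ix_(idx, idx)].astype(float)
    cov[np.diag_indices_from(cov)] += sigma2_e
    return cov


def oum_design_weights(
    tree: SpeciesTree, regime: Regime, alpha: float
) -> np.ndarray:
    """Weights W (n_taxa x n_optima) with E[tip] = W @ theta under OU.

    The expected tip value is the optimum of each root-path segment weighted
    by how much of the mean reversion happened inside it; the root optimum
    additionally carries the stationary root mean ``exp(-alpha T_i)``.
    Rows sum to one.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    n = tree.n_taxa
    W = np.zeros((n, regime.n_optima))
    depth = tree.node_depths()
    tip_depth = depth[:n]
    for i in range(n):
        W[i, 0] = np.exp(-alpha * tip_depth[i])
        d_near = 0.0
        for e in tree.root_path(i):
            d_far = d_near + tree.lengths[e]
            k = regime.optimum_index[e]
            W[i, k] += np.exp(-alpha * d_near) - np.exp(-alpha * d_far)
            d_near = d_far
    return W
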
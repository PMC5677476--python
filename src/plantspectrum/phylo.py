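"""Phylogenetic comparative machinery.

Covers Newick tree I/O, the Brownian-motion phylogenetic covariance matrix C
(C[i,j] = shared root-to-MRCA path length of tips i and j), Felsenstein's
phylogenetically independent contrasts by the pruning algorithm, GLS
phylogenetically corrected PCA of a species x trait matrix, the
eigenvalue-variance phenotypic integration index Var(lambda) =
sum((lambda_i - 1)^2) / N, and Kaiser-rule dimensionality (number of
eigenvalues strictly greater than 1).

Under Brownian motion the tip values of a trait are multivariate normal with
covariance proportional to C; the GLS ("evolutionary") covariance of a trait
matrix X is R = (X - 1a)' C^-1 (X - 1a) / (n - 1) with a the GLS root state
estimate.  Eigenanalysis of the corresponding correlation matrix yields axes
that are evolutionarily independent; on a star phylogeny the whole procedure
collapses to ordinary correlation PCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .errors import InsufficientDataError, PhylogenyError, ZeroVarianceContrastError

logger = logging.getLogger(__name__)


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, wrapping a dendropy Tree.

    Tip labels are the species identifiers used throughout the pipeline;
    matching against trait tables is exact and case-sensitive.
    """

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def newick(self) -> str:
        # .17g keeps branch lengths exact through a write/read round-trip
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".17g",
        )

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []
        for leaf in self.tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        return max(depths) - min(depths) <= tol


@dataclass
class ContrastSet:
    """Standardized independent contrasts for one trait.

    One contrast per internal node of a bifurcating tree (n_tips - 1 total),
    each divided by the square root of its expected variance (the sum of the
    two pruning-extended child branch lengths, stored in ``variances``).
    """

    contrasts: np.ndarray
    node_ids: list[str]
    variances: np.ndarray

    def __len__(self) -> int:
        return len(self.contrasts)


@dataclass
class PhyloPCAResult:
    """Output of a phylogenetically corrected PCA in correlation mode."""

    eigenvalues: np.ndarray
    loadings: pd.DataFrame          # traits x components, orthonormal
    scores: pd.DataFrame            # species x components
    evolutionary_correlation: pd.DataFrame
    integration_index: float
    dimensionality: int
    n_traits: int
    n_species: int
    dropped_species: list[str] = field(default_factory=list)


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a Phylogeny.

    Branch lengths are required on every non-root edge; polytomies are
    resolved into arbitrary bifurcations with zero-length internal edges
    (logged).  Underscores in labels are preserved verbatim.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhylogenyError(f"could not parse Newick input: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {lab for lab in labels if labels.count(lab) > 1}
    if dupes:
        raise PhylogenyError(f"duplicate tip labels: {sorted(dupes)}")

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            name = node.taxon.label if node.taxon else "<internal node>"
            raise PhylogenyError(f"missing branch length on edge above {name}")
        if node.edge.length < 0:
            name = node.taxon.label if node.taxon else "<internal node>"
            raise PhylogenyError(f"negative branch length above {name}")

    n_polytomies = sum(
        1 for nd in tree.preorder_node_iter() if len(nd.child_nodes()) > 2
    )
    if n_polytomies:
        tree.resolve_polytomies(limit=2, update_bipartitions=False)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                node.edge.length = 0.0
        logger.info("resolved %d polytomies with zero-length edges", n_polytomies)
    return Phylogeny(tree=tree)


def prune_to_species(phylogeny: Phylogeny, species: list[str]) -> Phylogeny:
    """Subtree induced by the given tip labels (path lengths preserved)."""
    missing = sorted(set(species) - set(phylogeny.tip_labels))
    if missing:
        raise PhylogenyError(f"species not on the tree: {missing}")
    pruned = phylogeny.tree.extract_tree_with_taxa_labels(labels=set(species))
    return Phylogeny(tree=pruned)


def phylo_vcv(phylogeny: Phylogeny) -> pd.DataFrame:
    """Phylogenetic covariance matrix C in branch-length units.

    C[i,j] is the depth (root-to-node path length) of the MRCA of tips i and
    j; the diagonal holds tip depths.  Scaling every branch length by k
    scales C by k.
    """
    tree = phylogeny.tree
    tips = list(tree.leaf_node_iter())
    labels = [t.taxon.label for t in tips]
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    C = np.zeros((n, n))

    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length

    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tipsets[id(node)] = [i]
            C[i, i] = depth[id(node)]
        else:
            children = node.child_nodes()
            sets = [tipsets[id(c)] for c in children]
            d = depth[id(node)]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        for j in sets[b]:
                            C[i, j] = C[j, i] = d
            tipsets[id(node)] = [i for s in sets for i in s]
    return pd.DataFrame(C, index=labels, columns=labels)


def compute_pics(phylogeny: Phylogeny, trait: pd.Series | dict) -> ContrastSet:
    """Felsenstein's independent contrasts by post-order pruning.

    At each internal node with child values x1, x2 on (extended) branches
    b1, b2 the standardized contrast is (x1 - x2) / sqrt(b1 + b2); the node
    is assigned the precision-weighted value (x1/b1 + x2/b2)/(1/b1 + 1/b2)
    and its parent branch is extended by b1*b2/(b1 + b2).  Zero-length
    sister branches (b1 + b2 = 0) are an error, not a silent epsilon.
    """
    values = dict(trait) if not isinstance(trait, dict) else dict(trait)
    tree = phylogeny.tree
    missing = [
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if leaf.taxon.label not in values or pd.isna(values[leaf.taxon.label])
    ]
    if missing:
        raise PhylogenyError(f"tips without trait values: {missing}")

    node_value: dict[int, float] = {}
    node_branch: dict[int, float] = {}
    contrasts: list[float] = []
    node_ids: list[str] = []
    variances: list[float] = []
    counter = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_value[id(node)] = float(values[node.taxon.label])
            node_branch[id(node)] = float(node.edge.length)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise PhylogenyError(
                "tree must be bifurcating for contrasts; resolve polytomies first"
            )
        c1, c2 = children
        x1, x2 = node_value[id(c1)], node_value[id(c2)]
        b1, b2 = node_branch[id(c1)], node_branch[id(c2)]
        v = b1 + b2
        if v <= 0:
            raise ZeroVarianceContrastError(
                "contrast with zero expected variance (both sister branches zero)"
            )
        counter += 1
        node_ids.append(node.label or f"node{counter}")
        contrasts.append((x1 - x2) / np.sqrt(v))
        variances.append(v)
        if b1 > 0 and b2 > 0:
            node_value[id(node)] = (x1 / b1 + x2 / b2) / (1 / b1 + 1 / b2)
        else:
            # a zero-length child branch pins the ancestral value to that child
            node_value[id(node)] = x1 if b1 == 0 else x2
        own = node.edge.length if node.parent_node is not None else 0.0
        node_branch[id(node)] = own + b1 * b2 / v
    return ContrastSet(
        contrasts=np.array(contrasts),
        node_ids=node_ids,
        variances=np.array(variances),
    )


def compute_pics_table(phylogeny: Phylogeny, traits: pd.DataFrame) -> pd.DataFrame:
    """Contrasts for every column of a species x trait table (shared node order)."""
    cols = {}
    node_ids = None
    for trait in traits.columns:
        cs = compute_pics(phylogeny, traits[trait])
        cols[trait] = cs.contrasts
        node_ids = cs.node_ids
    return pd.DataFrame(cols, index=node_ids)


def _gls_mean_and_cov(
    X: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS root-state estimate a and evolutionary covariance R under BM."""
    n = X.shape[0]
    try:
        factor = cho_factor(C)
    except LinAlgError as exc:
        raise PhylogenyError(
            "singular phylogenetic covariance; check for zero-length tip branches"
        ) from exc
    ones = np.ones(n)
    Ci1 = cho_solve(factor, ones)
    a = (Ci1 @ X) / (ones @ Ci1)
    Xc = X - a
    R = Xc.T @ cho_solve(factor, Xc) / (n - 1)
    return a, Xc, R


def phylo_pca(
    phylogeny: Phylogeny,
    traits,
    mode: str = "correlation",
) -> PhyloPCAResult:
    """Phylogenetically corrected PCA of species trait means.

    ``traits`` is a TraitTable or a species x trait DataFrame.  Species with
    any missing trait are dropped (complete-case, recorded in the result);
    the analysis requires at least N+1 species for N traits.  In the default
    correlation mode the GLS evolutionary covariance is standardized to unit
    diagonal before eigenanalysis, so the eigenvalues sum to N, and scores
    are the correspondingly standardized GLS-centered data projected on the
    eigenvectors.
    """
    data = traits.data if hasattr(traits, "data") else traits
    if mode not in ("correlation", "covariance"):
        raise ValueError("mode must be 'correlation' or 'covariance'")

    complete = data.dropna()
    dropped = sorted(set(data.index) - set(complete.index))
    if dropped:
        logger.info("phylo_pca: dropped %d incomplete species", len(dropped))

    tip_set = set(phylogeny.tip_labels)
    extra = sorted(set(complete.index) - tip_set)
    if extra:
        raise PhylogenyError(f"species not on the tree: {extra}")
    use = [t for t in phylogeny.tip_labels if t in set(complete.index)]
    n, N = len(use), data.shape[1]
    if n <= N:
        raise InsufficientDataError(
            f"need more species ({n}) than traits ({N}) for the GLS covariance"
        )

    C = phylo_vcv(phylogeny).loc[use, use].to_numpy()
    X = complete.loc[use].to_numpy(dtype=float)
    _, Xc, R = _gls_mean_and_cov(X, C)

    if mode == "correlation":
        sd = np.sqrt(np.diag(R))
        if np.any(sd == 0):
            bad = [data.columns[i] for i in np.flatnonzero(sd == 0)]
            raise InsufficientDataError(f"traits with zero evolutionary variance: {bad}")
        M = R / np.outer(sd, sd)
        Xs = Xc / sd
    else:
        M = R
        Xs = Xc

    eigenvalues, eigenvectors = np.linalg.eigh((M + M.T) / 2.0)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    if np.any(eigenvalues < -1e-10):
        raise PhylogenyError(
            f"evolutionary correlation matrix has negative eigenvalue {eigenvalues.min():.3e}"
        )
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    # deterministic sign convention: largest-|loading| entry positive
    for j in range(eigenvectors.shape[1]):
        k = np.argmax(np.abs(eigenvectors[:, j]))
        if eigenvectors[k, j] < 0:
            eigenvectors[:, j] *= -1

    comp_names = [f"PC{i+1}" for i in range(N)]
    loadings = pd.DataFrame(eigenvectors, index=data.columns, columns=comp_names)
    scores = pd.DataFrame(Xs @ eigenvectors, index=use, columns=comp_names)
    corr = pd.DataFrame(M, index=data.columns, columns=data.columns)
    if mode == "correlation":
        index = integration_index(eigenvalues)
    else:
        index = float(np.mean((eigenvalues - eigenvalues.mean()) ** 2))
    return PhyloPCAResult(
        eigenvalues=eigenvalues,
        loadings=loadings,
        scores=scores,
        evolutionary_correlation=corr,
        integration_index=index,
        dimensionality=kaiser_dimensionality(eigenvalues),
        n_traits=N,
        n_species=n,
        dropped_species=dropped,
    )


def integration_index(eigenvalues) -> float:
    """Phenotypic integration index: variance of correlation-matrix eigenvalues.

    Var(lambda) = sum((lambda_i - 1)^2) / N, zero for mutually uncorrelated
    traits and N - 1 when a single axis absorbs all variance.  Warns if the
    eigenvalues do not sum to N (i.e. did not come from a correlation matrix).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    N = lam.size
    if abs(lam.sum() - N) > 1e-6:
        warnings.warn(
            "eigenvalues do not sum to the trait count; integration index "
            "assumes correlation-matrix input"
        )
    return float(np.mean((lam - 1.0) ** 2))


def kaiser_dimensionality(eigenvalues) -> int:
    """Number of eigenvalues strictly greater than 1 (Kaiser's rule)."""
    lam = np.asarray(eigenvalues, dtype=float)
    count = int(np.sum(lam > 1.0))
    if count == 0:
        warnings.warn("degenerate spectrum: no eigenvalue exceeds 1")
    return count
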
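"""Whole-profile comparison of lab and field samples.

The marker-gene-set expression profiles of lab replicates and field samples
are compared as ecological community profiles: Bray-Curtis dissimilarity on
relative abundances, agglomerative clustering with the Ward.D2 criterion,
and a similarity-profile (SIMPROF) permutation test applied recursively
down the dendrogram to decide which clusters reflect real structure rather
than sampling noise.

SIMPROF (Clarke, Somerfield & Gorley) asks whether a group of samples shows
more internal similarity structure than expected if each transcript's
abundances were exchangeable across samples.  The observed profile is the
sorted vector of pairwise similarities; null profiles are built by
permuting each transcript's values independently across the group's
samples.  The test statistic pi sums the absolute deviations of the
observed profile from the mean null profile; its p-value comes from a
second, independent set of permutations.

Ward.D2 is applied directly to Bray-Curtis dissimilarities.  Bray-Curtis is
not Euclidean, so the variance interpretation of Ward's criterion is only
approximate; this mirrors common ecological practice and is documented as a
caveat rather than "corrected".
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .countmatrix import CountMatrix, normalize_relative
from .markers import MarkerCatalog, STRESS_CONDITION


# -- Bray-Curtis -------------------------------------------------------------


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, CountMatrix):
        return matrix.values
    return pd.DataFrame(matrix)


def bray_curtis(matrix) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples (columns).

    ``D(j, k) = sum_t |x_tj - x_tk| / sum_t (x_tj + x_tk)``; symmetric,
    zero-diagonal, bounded in [0, 1].  Raises when two all-zero samples
    make the dissimilarity undefined.
    """
    values = _as_frame(matrix)
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative abundances")
    zero_cols = values.columns[arr.sum(axis=0) == 0].tolist()
    if len(zero_cols) >= 2:
        raise ValueError(f"dissimilarity undefined between all-zero samples: {zero_cols}")
    d = squareform(pdist(arr.T, metric="braycurtis"))
    return pd.DataFrame(d, index=values.columns, columns=values.columns)


# -- Ward.D2 dendrogram ------------------------------------------------------


@dataclass
class DendroNode:
    """Node of a binary merge tree; leaves carry sample names."""

    height: float
    members: tuple[str, ...]
    name: str | None = None
    left: "DendroNode | None" = None
    right: "DendroNode | None" = None
    # SIMPROF annotations, filled in by simprof()
    tested: bool = False
    pi: float | None = None
    p_value: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def internal_nodes(self) -> list["DendroNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def merge_order(self) -> list[tuple[tuple[str, ...], float]]:
        """(member set, height) of every merge, in ascending height order."""
        merges = [(n.members, n.height) for n in self.internal_nodes()]
        return sorted(merges, key=lambda m: (m[1], m[0]))


def ward_cluster(D: pd.DataFrame) -> DendroNode:
    """Agglomerative clustering under the Ward.D2 criterion.

    Uses the Lance-Williams recurrence on squared dissimilarities,

        d(i u j, k) = sqrt[((n_i + n_k) d_ik^2 + (n_j + n_k) d_jk^2
                            - n_k d_ij^2) / (n_i + n_j + n_k)],

    merging the closest pair at each step.  Exact distance ties break
    deterministically on the lexicographically smallest pair of cluster
    labels, a cluster's label being its sorted member tuple.
    """
    arr = np.asarray(D, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    labels = [str(c) for c in D.columns] if isinstance(D, pd.DataFrame) else [
        f"S{i}" for i in range(arr.shape[0])
    ]
    if len(labels) < 2:
        raise ValueError("need at least two samples to cluster")

    nodes = [DendroNode(height=0.0, members=(lab,), name=lab) for lab in labels]
    sizes = [1] * len(nodes)
    dist = arr.copy()

    while len(nodes) > 1:
        best = None
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                key = (dist[i, j], min(nodes[i].members, nodes[j].members),
                       max(nodes[i].members, nodes[j].members))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        d_ij = dist[i, j]
        merged = DendroNode(
            height=float(d_ij),
            members=tuple(sorted(nodes[i].members + nodes[j].members)),
            left=nodes[i],
            right=nodes[j],
        )
        n_i, n_j = sizes[i], sizes[j]
        new_row = np.empty(len(nodes))
        for k in range(len(nodes)):
            if k in (i, j):
                continue
            n_k = sizes[k]
            num = (
                (n_i + n_k) * dist[i, k] ** 2
                + (n_j + n_k) * dist[j, k] ** 2
                - n_k * d_ij ** 2
            )
            new_row[k] = np.sqrt(max(num / (n_i + n_j + n_k), 0.0))
        keep = [k for k in range(len(nodes)) if k not in (i, j)]
        dist = dist[np.ix_(keep, keep)]
        row = new_row[keep]
        dist = np.block([
            [dist, row[:, None]],
            [row[None, :], np.zeros((1, 1))],
        ])
        nodes = [nodes[k] for k in keep] + [merged]
        sizes = [sizes[k] for k in keep] + [n_i + n_j]

    return nodes[0]


# -- SIMPROF -----------------------------------------------------------------


@dataclass
class SimprofResult:
    """Recursive SIMPROF outcome over a Ward.D2 dendrogram.

    ``clusters`` are the maximal groups within which no significant
    structure was found (where the recursive descent stopped);
    ``significant_nodes`` are the tested nodes whose null hypothesis of
    exchangeability was rejected.  Per-node statistics are also annotated
    on the dendrogram nodes themselves.
    """

    dendrogram: DendroNode
    clusters: list[tuple[str, ...]]
    significant_nodes: list[DendroNode] = dataclass_field(default_factory=list)
    alpha: float = 0.05
    n_expected: int = 999
    n_simulated: int = 999
    seed: int = 0

    @property
    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "members": ";".join(n.members),
                "height": n.height,
                "pi": n.pi,
                "p_value": n.p_value,
                "significant": n.p_value is not None and n.p_value <= self.alpha,
            }
            for n in self.dendrogram.internal_nodes()
            if n.tested
        ]
        return pd.DataFrame(rows, columns=["members", "height", "pi", "p_value", "significant"])


def _group_rng(seed: int, members: tuple[str, ...]) -> np.random.Generator:
    """Permutation stream keyed by the sample set, not by column order.

    Deriving the stream from the sorted member names makes the test's
    permutations -- hence pi and p -- invariant to the input's sample order.
    """
    digest = zlib.crc32("|".join(sorted(members)).encode())
    return np.random.default_rng([seed, digest])


def _similarity_profile(arr: np.ndarray) -> np.ndarray:
    """Sorted pairwise Bray-Curtis similarities of the columns of arr."""
    return np.sort(1.0 - pdist(arr.T, metric="braycurtis"))


def simprof_test(
    values: pd.DataFrame,
    members: tuple[str, ...],
    n_expected: int,
    n_simulated: int,
    seed: int,
) -> tuple[float, float]:
    """One SIMPROF test of a sample group; returns (pi, p_value).

    ``values`` is the full transcripts x samples relative-abundance table;
    only the ``members`` columns enter the test.  Rows and columns are
    sorted by ID first so the outcome does not depend on input order.
    The p-value uses the plus-one rule, (count >= pi_obs + 1) /
    (n_simulated + 1), and therefore can never be exactly zero.
    """
    cols = sorted(members)
    sub = values.loc[sorted(values.index), cols].to_numpy(dtype=float)
    rng = _group_rng(seed, members)

    obs = _similarity_profile(sub)
    null_profiles = np.empty((n_expected, obs.size))
    for b in range(n_expected):
        null_profiles[b] = _similarity_profile(rng.permuted(sub, axis=1))
    mean_profile = null_profiles.mean(axis=0)
    pi_obs = float(np.abs(obs - mean_profile).sum())

    exceed = 0
    for b in range(n_simulated):
        prof = _similarity_profile(rng.permuted(sub, axis=1))
        pi_b = float(np.abs(prof - mean_profile).sum())
        if pi_b >= pi_obs:
            exceed += 1
    p = (exceed + 1) / (n_simulated + 1)
    return pi_obs, p


def simprof(
    matrix,
    alpha: float = 0.05,
    n_expected: int = 999,
    n_simulated: int = 999,
    seed: int = 0,
) -> SimprofResult:
    """Ward.D2 clustering with recursive SIMPROF significance pruning.

    The root group is always tested (when it has >= 3 samples; smaller
    groups are untestable and terminal).  The descent continues only into
    children of significant nodes; maximal groups without significant
    internal structure become the reported clusters.  Deterministic under
    ``seed``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    values = _as_frame(matrix)
    D = bray_curtis(values)
    tree = ward_cluster(D)

    clusters: list[tuple[str, ...]] = []
    significant: list[DendroNode] = []

    def visit(node: DendroNode) -> None:
        if len(node.members) < 3:
            clusters.append(node.members)
            return
        node.pi, node.p_value = simprof_test(
            values, node.members, n_expected, n_simulated, seed
        )
        node.tested = True
        if node.p_value <= alpha:
            significant.append(node)
            visit(node.left)
            visit(node.right)
        else:
            clusters.append(node.members)

    visit(tree)
    clusters.sort()
    return SimprofResult(
        dendrogram=tree,
        clusters=clusters,
        significant_nodes=significant,
        alpha=alpha,
        n_expected=n_expected,
        n_simulated=n_simulated,
        seed=seed,
    )


# -- dataset assembly --------------------------------------------------------


@dataclass(frozen=True)
class DatasetSpec:
    """Which transcripts enter the lab-vs-field profile comparison.

    ``dataset1``: only the single-stressor regulated transcripts used for
    ratio calculation.  ``dataset2``: all regulated transcripts including
    dual-regulated ones (a strict superset).  ``transcript_ids`` overrides
    the catalog-derived selection when given.
    """

    variant: str  # dataset1 | dataset2
    stressor: str
    transcript_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("dataset1", "dataset2"):
            raise ValueError(f"unknown dataset variant {self.variant!r}")


def dataset_transcripts(catalog: MarkerCatalog, spec: DatasetSpec) -> list[str]:
    if spec.transcript_ids is not None:
        return sorted(spec.transcript_ids)
    ids = set(catalog.regulated_ids(spec.stressor))
    if spec.variant == "dataset2":
        ids |= set(catalog.dual_ids())
    return sorted(ids)


def build_dataset(
    catalog: MarkerCatalog,
    field_table: CountMatrix,
    lab_matrix: CountMatrix,
    spec: DatasetSpec,
) -> CountMatrix:
    """Combine lab (control + stress) and field samples over one marker set.

    The result is restricted to the spec's transcripts, concatenates lab
    replicates of the control and stress conditions with the field
    replicates, and renormalizes every column to relative abundances so lab
    and field profiles are on a common scale.
    """
    ids = dataset_transcripts(catalog, spec)
    if not ids:
        raise ValueError(f"no transcripts selected for {spec.variant}/{spec.stressor}")
    for name, table in (("lab", lab_matrix), ("field", field_table)):
        missing = [t for t in ids if t not in table.values.index]
        if missing:
            raise ValueError(f"transcripts absent from {name} table: {missing}")
    condition = STRESS_CONDITION[spec.stressor]
    lab_cols = lab_matrix.condition_samples("control") + lab_matrix.condition_samples(condition)
    if not lab_cols:
        raise ValueError("lab matrix has no control or stress samples")
    lab_sub = lab_matrix.subset_samples(lab_cols).subset_transcripts(ids)
    field_sub = field_table.subset_transcripts(ids)
    values = pd.concat([lab_sub.values, field_sub.values], axis=1)
    samples = pd.concat([lab_sub.samples, field_sub.samples])
    return normalize_relative(CountMatrix(values, samples))


# -- Newick export -----------------------------------------------------------


def _quote(name: str) -> str:
    if any(ch in name for ch in " \t()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def render_newick(tree: DendroNode, result: SimprofResult | None = None) -> str:
    """Serialize a dendrogram as Newick with p-value node labels.

    Branch lengths are height differences between parent and child (leaves
    sit at height zero).  Tested internal nodes carry a label of the form
    ``p=0.012`` so the significance annotation survives round-trips through
    standard Newick parsers.
    """

    def label(node: DendroNode) -> str:
        if node.tested and node.p_value is not None:
            return _quote(f"p={node.p_value:.9g}")
        return ""

    def fmt(node: DendroNode, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf else node.height)
        if node.is_leaf:
            return f"{_quote(node.name)}:{length:.9g}"
        inner = f"({fmt(node.left, node.height)},{fmt(node.right, node.height)})"
        return f"{inner}{label(node)}:{length:.9g}"

    if tree.is_leaf:
        return f"{_quote(tree.name)}:0;"
    inner = f"({fmt(tree.left, tree.height)},{fmt(tree.right, tree.height)})"
    return f"{inner}{label(tree)};"
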
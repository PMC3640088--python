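"""Dataset-wide identification QC: UPGMA dendrogram, NMDS ordination, and
taxon concordance flags.

These are heuristics for rapid estimation of data quality, not species
identification: a specimen whose sequence clusters inside another genus's
clade is flagged for manual scrutiny (misidentification, mixed sample or
nomenclatural issue), and a taxon whose accessions scatter over a clade much
larger than themselves is flagged as a split group (polyphyly or distance
artifact).

Non-retained (censored) pairs have no trustworthy distance.  UPGMA needs a
complete matrix, so censored pairs default to ``threshold_bp + 1`` — "far",
just above the retention cap, without fabricating precision.  NMDS can work
with missing data directly: censored pairs are simply excluded from the
stress sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .distance import SparseDistanceMatrix
from .records import Dataset


# --- UPGMA ---------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an ultrametric merge tree; leaves carry specimen ids."""

    height: float
    name: Optional[str] = None
    children: tuple["TreeNode", ...] = ()
    leafset: frozenset[str] = frozenset()

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Dendrogram:
    root: TreeNode
    ids: list[str]
    linkage: np.ndarray  # scipy-style (n-1, 4): idx_a, idx_b, avg distance, size

    def leaves(self) -> frozenset[str]:
        return self.root.leafset

    def nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def minimal_clade(self, leaf_ids) -> TreeNode:
        """Smallest clade containing every id in *leaf_ids*."""
        target = frozenset(leaf_ids)
        if not target <= self.root.leafset:
            raise KeyError(f"unknown leaves: {sorted(target - self.root.leafset)}")
        node = self.root
        while True:
            nxt = [c for c in node.children if target <= c.leafset]
            if not nxt:
                return node
            node = nxt[0]

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6g}"

        if self.root.is_leaf:
            return f"{self.root.name};"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def dense_distances(matrix: SparseDistanceMatrix, missing_policy: str = "censor") -> tuple[np.ndarray, list[str]]:
    """Square distance array with censored pairs filled per *missing_policy*.

    ``censor`` sets them to ``threshold_bp + 1``; ``drop`` greedily removes
    the specimens with the most censored pairs until the matrix is complete.
    """
    ids = list(matrix.ids)
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    d = np.zeros((n, n))
    missing_count = np.zeros(n, dtype=int)
    for (a, b), p in matrix.nonretained.items():
        missing_count[index[a]] += 1
        missing_count[index[b]] += 1
        d[index[a], index[b]] = d[index[b], index[a]] = matrix.threshold_bp + 1
    for (a, b), p in matrix.entries.items():
        d[index[a], index[b]] = d[index[b], index[a]] = p.bp_diff
    if missing_policy == "censor" or not missing_count.any():
        return d, ids
    if missing_policy == "drop":
        keep = np.ones(n, dtype=bool)
        nonret = [(index[a], index[b]) for a, b in matrix.nonretained]
        while True:
            open_pairs = [(i, j) for i, j in nonret if keep[i] and keep[j]]
            if not open_pairs:
                break
            counts = np.zeros(n, dtype=int)
            for i, j in open_pairs:
                counts[i] += 1
                counts[j] += 1
            keep[int(np.argmax(counts))] = False
        sel = np.flatnonzero(keep)
        return d[np.ix_(sel, sel)], [ids[i] for i in sel]
    raise ValueError(f"unknown missing_policy {missing_policy!r}")


def upgma(matrix: SparseDistanceMatrix, missing_policy: str = "censor") -> Dendrogram:
    """Unweighted pair-group average clustering with deterministic tie-breaks.

    Merge heights are half the average inter-cluster distance (ultrametric
    leaf-to-node depth).  Among equally close cluster pairs the pair whose
    (lexicographically smallest members) sort first is merged, making output
    independent of input order.
    """
    d, ids = dense_distances(matrix, missing_policy)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 specimens")
    active: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, name=ids[i], leafset=frozenset([ids[i]])) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    scipy_index = {i: i for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]
    linkage_rows = []
    next_id = n
    min_member = {i: ids[i] for i in range(n)}
    while len(active) > 1:
        best = None
        best_key = None
        for (i, j), dij in dist.items():
            key = (dij, *sorted((min_member[i], min_member[j])))
            if best_key is None or key < best_key:
                best_key = key
                best = (i, j)
        i, j = best
        dij = dist[(i, j)]
        node = TreeNode(
            height=dij / 2.0,
            children=tuple(sorted((active[i], active[j]), key=lambda c: min(c.leafset))),
            leafset=active[i].leafset | active[j].leafset,
        )
        linkage_rows.append([scipy_index[i], scipy_index[j], dij, sizes[i] + sizes[j]])
        new = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(new, k), max(new, k))] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        del dist[(i, j)]
        sizes[new] = sizes[i] + sizes[j]
        min_member[new] = min(min_member[i], min_member[j])
        scipy_index[new] = n + len(linkage_rows) - 1
        active[new] = node
        for k in (i, j):
            del active[k], sizes[k], min_member[k], scipy_index[k]
    root = next(iter(active.values()))
    return Dendrogram(root=root, ids=ids, linkage=np.array(linkage_rows))


# --- NMDS ----------------------------------------------------------------------

@dataclass
class OrdinationResult:
    ids: list[str]
    coordinates: np.ndarray  # (n, dims)
    stress: float
    n_iter: int
    converged: bool
    stress_history: list[float] = field(default_factory=list)


def _stress1(d: np.ndarray, dhat: np.ndarray, w: np.ndarray) -> float:
    num = float(np.sum(w * (d - dhat) ** 2))
    den = float(np.sum(w * d ** 2))
    return np.sqrt(num / den) if den > 0 else 0.0


def nmds(
    matrix: SparseDistanceMatrix,
    dims: int = 2,
    n_starts: int = 8,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    missing_policy: str = "censor",
) -> OrdinationResult:
    """Nonmetric MDS minimizing Kruskal stress-1.

    Each start draws a random configuration, then alternates a monotone
    (isotonic) regression of configuration distances on dissimilarity ranks
    with a weighted Guttman update.  Censored pairs are handled per
    *missing_policy*: ``censor`` (default) enters them at threshold+1 — only
    their rank matters, and "beyond the cap" is exactly what is known about
    them; ``exclude`` gives them weight 0 so they never enter the stress sum
    (with heavily censored data this leaves group placement unconstrained).
    The best-stress start wins; non-convergence is reported, not fatal.
    """
    ids = list(matrix.ids)
    n = len(ids)
    if n < 4:
        raise ValueError("need at least 4 specimens for an NMDS ordination")
    index = {s: i for i, s in enumerate(ids)}
    m = n * (n - 1) // 2

    def flat(i: int, j: int) -> int:
        i, j = min(i, j), max(i, j)
        return m - (n - i) * (n - i - 1) // 2 + (j - i - 1)

    delta = np.zeros(m)
    w = np.zeros(m)
    for (a, b), p in matrix.entries.items():
        k = flat(index[a], index[b])
        delta[k] = p.bp_diff
        w[k] = 1.0
    if missing_policy == "censor":
        for (a, b) in matrix.nonretained:
            k = flat(index[a], index[b])
            delta[k] = matrix.threshold_bp + 1
            w[k] = 1.0
    elif missing_policy != "exclude":
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if w.sum() < 3:
        raise ValueError("too few retained pairs for an ordination")

    order = np.argsort(delta[w > 0], kind="stable")
    active = np.flatnonzero(w > 0)

    # weighted Laplacian of the pair graph, pseudo-inverted once
    V = -squareform(w)
    np.fill_diagonal(V, -V.sum(axis=1))
    Vp = np.linalg.pinv(V)

    rng = np.random.default_rng(seed)
    best: Optional[OrdinationResult] = None
    scale = max(delta.max(), 1.0)
    for _start in range(n_starts):
        X = rng.normal(scale=scale, size=(n, dims))
        prev = np.inf
        history: list[float] = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            d = pdist(X)
            d = np.maximum(d, 1e-12)
            dhat = np.zeros(m)
            iso = isotonic_regression(d[active][order]).x
            dhat_active = np.empty_like(iso)
            dhat_active[order] = iso
            dhat[active] = dhat_active
            stress = _stress1(d, dhat, w)
            history.append(stress)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # weighted Guttman transform
            ratio = np.zeros(m)
            ratio[active] = dhat[active] / d[active]
            B = -squareform(ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X = Vp @ (B @ X)
        result = OrdinationResult(
            ids=ids, coordinates=X, stress=history[-1], n_iter=n_iter,
            converged=converged, stress_history=history,
        )
        if best is None or result.stress < best.stress:
            best = result
    return best


# --- concordance flags -----------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceFlag:
    specimen_id: str
    level: str       # genus | family
    flag_type: str   # foreign_inclusion | split_group
    taxon: str       # the taxon whose clade raised the flag
    context: str


def _taxon_of(record, level: str) -> str:
    if level == "genus":
        return record.genus
    if level == "family":
        return record.family
    raise ValueError("level must be 'genus' or 'family'")


def concordance_flags(
    dendrogram: Dendrogram,
    dataset: Dataset,
    level: str = "genus",
    dilation_factor: float = 3.0,
) -> list[ConcordanceFlag]:
    """Flag specimens discordant with their taxon's placement in the tree.

    For every taxon at *level* with ≥2 accessions in the tree, the smallest
    clade containing all of them is found.  Specimens of other taxa inside
    that clade are flagged ``foreign_inclusion``; a taxon whose minimal clade
    holds more than ``dilation_factor`` times its own accessions is flagged
    ``split_group`` (the multiple-cluster symptom).  Flags are invariant to
    input order.
    """
    leaves = dendrogram.leaves()
    members: dict[str, set[str]] = {}
    for rec in dataset.records:
        if rec.specimen_id not in leaves:
            continue
        taxon = _taxon_of(rec, level)
        if taxon:
            members.setdefault(taxon, set()).add(rec.specimen_id)
    flags: list[ConcordanceFlag] = []
    for taxon in sorted(members):
        own = members[taxon]
        if len(own) < 2:
            continue
        clade = dendrogram.minimal_clade(own)
        foreign = sorted(clade.leafset - own)
        context = f"minimal clade of {taxon} ({level}): {len(clade.leafset)} leaves, {len(own)} own"
        for sid in foreign:
            flags.append(ConcordanceFlag(sid, level, "foreign_inclusion", taxon, context))
        if len(clade.leafset) > dilation_factor * len(own):
            flags.append(ConcordanceFlag(min(own), level, "split_group", taxon, context))
    return flags


def ordination_coherence(
    ordination: OrdinationResult,
    dataset: Dataset,
    level: str = "genus",
) -> dict[str, float]:
    """Per-taxon tightness in the ordination plane.

    Score = mean within-taxon point distance / mean distance from the taxon's
    points to all other points; lower is tighter, ~1 means no structure.
    Taxa with <2 accessions are skipped.
    """
    index = {s: i for i, s in enumerate(ordination.ids)}
    coords = ordination.coordinates
    groups: dict[str, list[int]] = {}
    for rec in dataset.records:
        if rec.specimen_id not in index:
            continue
        taxon = _taxon_of(rec, level)
        if taxon:
            groups.setdefault(taxon, []).append(index[rec.specimen_id])
    scores: dict[str, float] = {}
    all_idx = np.arange(len(ordination.ids))
    for taxon, idxs in sorted(groups.items()):
        if len(idxs) < 2:
            continue
        idxs = np.array(idxs)
        pts = coords[idxs]
        within = pdist(pts)
        others = np.setdiff1d(all_idx, idxs)
        if others.size == 0:
            continue
        cross = np.linalg.norm(pts[:, None, :] - coords[others][None, :, :], axis=2)
        denom = float(cross.mean())
        scores[taxon] = float(within.mean()) / denom if denom > 0 else np.inf
    return scores
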
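"""Clustering of organisms and samples by affinity propagation.

Affinity propagation (AP) picks exemplars — real data points that
represent clusters — by exchanging responsibility and availability
messages over a similarity matrix. The diagonal ("preference") controls
how readily points become exemplars, and hence how many clusters emerge:
high preferences fragment the data into singletons, very low preferences
collapse it into one cluster. The workflow here mirrors common practice
with AP: compute a Pearson or Bray-Curtis similarity between units, run
AP, agglomerate the resulting clusters into a merge tree for inspection,
and tune the preference by bisection toward a desired cluster count.

The objective AP heuristically maximizes is the *net similarity*: the sum
of each non-exemplar's similarity to its exemplar plus the preferences of
the exemplars. `net_similarity_of` computes it for any exemplar
assignment, which makes small instances checkable against exhaustive
search over exemplar subsets (see `brute_force_exemplars`).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .feature_matrices import (
    FeatureMatrix,
    MatrixError,
    normalize_per_million,
)

__all__ = [
    "SimilarityMatrix",
    "ClusteringResult",
    "Dendrogram",
    "ClusteringError",
    "similarity",
    "affinity_propagation",
    "net_similarity_of",
    "brute_force_exemplars",
    "agglomerate_clusters",
    "tune_preference",
    "robustness_leave_genus_out",
]


class ClusteringError(ValueError):
    pass


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity between labeled units."""

    labels: list[str]
    values: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ClusteringError("similarity matrix must be square and match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ClusteringError("similarity matrix must be symmetric within 1e-9")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(self.n, dtype=bool)
        return self.values[mask]


@dataclass
class ClusteringResult:
    """Outcome of one affinity propagation run."""

    labels: list[str]
    exemplar_of: dict[str, str]
    preference: float
    net_similarity: float
    converged: bool
    iterations: int

    @property
    def n_clusters(self) -> int:
        return len(set(self.exemplar_of.values()))

    @property
    def cluster_labels(self) -> np.ndarray:
        """Integer cluster index per unit, ordered as ``labels``."""
        exemplars = sorted(set(self.exemplar_of.values()))
        ix = {e: i for i, e in enumerate(exemplars)}
        return np.array([ix[self.exemplar_of[u]] for u in self.labels])

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": self.labels,
                "exemplar_of": self.exemplar_of,
                "preference": self.preference,
                "n_clusters": self.n_clusters,
                "net_similarity": self.net_similarity,
                "converged": self.converged,
                "iterations": self.iterations,
            },
            indent=2,
            sort_keys=True,
        )


def similarity(
    m: FeatureMatrix, measure: str = "pearson", axis: str = "columns"
) -> SimilarityMatrix:
    """Pairwise similarity between units (columns) or features (rows).

    ``pearson`` gives the correlation coefficient in [-1, 1];
    ``bray_curtis`` gives 1 minus the Bray-Curtis dissimilarity, in
    [0, 1] for non-negative data. Pearson is undefined for constant
    vectors, which are reported by label.
    """
    if axis == "columns":
        labels, vectors = m.col_ids, m.values.T
    elif axis == "rows":
        labels, vectors = m.row_ids, m.values
    else:
        raise ClusteringError(f"unknown axis {axis!r}")
    if len(labels) < 2:
        raise ClusteringError("similarity needs at least 2 units")
    if measure == "pearson":
        sd = vectors.std(axis=1)
        constant = [lab for lab, s in zip(labels, sd) if s == 0]
        if constant:
            raise ClusteringError(
                f"constant vector(s) under pearson: {', '.join(constant)}"
            )
        values = np.corrcoef(vectors)
        np.clip(values, -1.0, 1.0, out=values)
    elif measure == "bray_curtis":
        if (vectors < 0).any():
            raise ClusteringError("bray_curtis requires non-negative data")
        values = 1.0 - squareform(pdist(vectors, metric="braycurtis"))
    else:
        raise ClusteringError(f"unknown similarity measure {measure!r}")
    values = (values + values.T) / 2.0
    return SimilarityMatrix(labels=list(labels), values=values, measure=measure)


def net_similarity_of(
    s: SimilarityMatrix, exemplar_index: np.ndarray, preference: float
) -> float:
    """Net similarity of an assignment: sum of similarities to exemplars
    plus the exemplars' preferences."""
    total = 0.0
    for i, e in enumerate(exemplar_index):
        total += preference if i == e else s.values[i, e]
    return float(total)


def brute_force_exemplars(
    s: SimilarityMatrix, preference: float, k: Optional[int] = None
) -> tuple[np.ndarray, float]:
    """Exhaustive search for the exemplar subset maximizing net similarity.

    Feasible for ~10 points; serves as the exact oracle for AP. If ``k``
    is given only subsets of that size are searched.
    """
    n = s.n
    best: tuple[float, tuple[int, ...]] | None = None
    sizes = [k] if k is not None else range(1, n + 1)
    for size in sizes:
        for subset in itertools.combinations(range(n), size):
            sub = np.array(subset)
            assign = sub[np.argmax(s.values[:, sub], axis=1)]
            assign[sub] = sub
            # a subset is only valid if every chosen exemplar keeps itself
            score = sum(
                preference if i == e else s.values[i, e]
                for i, e in enumerate(assign)
            )
            if best is None or score > best[0]:
                best = (score, tuple(assign))
    assert best is not None
    return np.array(best[1]), float(best[0])


def affinity_propagation(
    s: SimilarityMatrix,
    preference: float,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_window: int = 100,
    seed: int = 0,
) -> ClusteringResult:
    """Affinity propagation by damped responsibility/availability passing.

    The diagonal of the similarity matrix is set to ``preference``; a tiny
    symmetric seeded noise (scale 1e-12) breaks exact-tie degeneracies.
    Exemplar decisions stable over ``convergence_window`` consecutive
    iterations terminate the run; otherwise the result is returned with
    ``converged=False``. Deterministic given the seed.
    """
    if not 0.5 <= damping < 1.0:
        raise ClusteringError("damping must lie in [0.5, 1)")
    if max_iter < convergence_window:
        raise ClusteringError("max_iter must be >= convergence_window")
    n = s.n
    if n == 1:
        lab = s.labels[0]
        return ClusteringResult(
            labels=[lab],
            exemplar_of={lab: lab},
            preference=preference,
            net_similarity=preference,
            converged=True,
            iterations=0,
        )
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, n))
    S = s.values + 1e-12 * (noise + noise.T) / 2.0
    np.fill_diagonal(S, preference)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    ind = np.arange(n)
    stable_for = 0
    last_exemplars: Optional[frozenset[int]] = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        first_ix = np.argmax(AS, axis=1)
        first = AS[ind, first_ix]
        AS[ind, first_ix] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[ind, first_ix] = S[ind, first_ix] - second
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, R.diagonal())
        col = Rp.sum(axis=0)
        Anew = col[None, :] - Rp
        diag = Anew.diagonal().copy()
        Anew = np.minimum(Anew, 0.0)
        np.fill_diagonal(Anew, diag)
        A = damping * A + (1 - damping) * Anew

        exemplars = frozenset(np.flatnonzero((A + R).diagonal() > 0))
        if exemplars and exemplars == last_exemplars:
            stable_for += 1
            if stable_for >= convergence_window:
                converged = True
                break
        else:
            stable_for = 0
        last_exemplars = exemplars

    ex = np.flatnonzero((A + R).diagonal() > 0)
    if len(ex) == 0:
        # degenerate: fall back to the single best candidate exemplar
        ex = np.array([int(np.argmax((A + R).diagonal()))])
    assign = ex[np.argmax(S[:, ex], axis=1)]
    assign[ex] = ex
    labels = s.labels
    exemplar_of = {labels[i]: labels[int(e)] for i, e in enumerate(assign)}
    return ClusteringResult(
        labels=list(labels),
        exemplar_of=exemplar_of,
        preference=preference,
        net_similarity=net_similarity_of(s, assign, preference),
        converged=converged,
        iterations=iterations,
    )


@dataclass
class Dendrogram:
    """Merge tree over affinity propagation clusters.

    ``merges`` records, from ``n_clusters`` leaves down to a single root,
    tuples of (cluster_a, cluster_b, height, merged_members); cluster ids
    are the exemplar labels of the AP clusters or synthetic ``merge<i>``
    ids for internal nodes. Heights are monotone non-decreasing.
    """

    leaves: dict[str, list[str]]
    merges: list[tuple[str, str, float, str]] = field(default_factory=list)
    _members: dict[str, list[str]] = field(default_factory=dict)

    def cut(self, k: int) -> dict[str, int]:
        """Labels for any k between 1 and the number of AP clusters."""
        n = len(self.leaves)
        if not 1 <= k <= n:
            raise ClusteringError(f"cut level k={k} outside [1, {n}]")
        clusters: dict[str, list[str]] = {c: list(m) for c, m in self.leaves.items()}
        for a, b, _h, new in self.merges[: n - k]:
            clusters[new] = clusters.pop(a) + clusters.pop(b)
        out: dict[str, int] = {}
        for i, cid in enumerate(sorted(clusters)):
            for unit in clusters[cid]:
                out[unit] = i
        return out

    def cut_table(self) -> str:
        """TSV with one row per unit and one column per cut level k."""
        n = len(self.leaves)
        units = sorted(u for m in self.leaves.values() for u in m)
        cuts = {k: self.cut(k) for k in range(1, n + 1)}
        lines = ["unit\t" + "\t".join(f"k{k}" for k in range(1, n + 1))]
        for u in units:
            lines.append(u + "\t" + "\t".join(str(cuts[k][u]) for k in range(1, n + 1)))
        return "\n".join(lines) + "\n"


def agglomerate_clusters(s: SimilarityMatrix, c: ClusteringResult) -> Dendrogram:
    """Exemplar-based agglomeration of AP clusters into a merge tree.

    At each step the pair of clusters whose union admits the best joint
    exemplar — the candidate member maximizing the mean similarity of all
    union members to it — is merged. Heights are the negated joint scores,
    made monotone by running maximum.
    """
    if c.n_clusters < 2:
        raise ClusteringError("agglomeration needs at least 2 clusters")
    ix = {lab: i for i, lab in enumerate(s.labels)}

    def joint_score(members: list[str]) -> float:
        # best joint exemplar: the member whose *worst* similarity to the
        # other members is largest. Judging a candidate exemplar by its
        # least-well-represented member keeps a large tight cluster from
        # absorbing a stray singleton that a small cluster fits better
        rows = np.array([ix[u] for u in members])
        sub = s.values[np.ix_(rows, rows)].astype(float)
        np.fill_diagonal(sub, np.inf)
        return float(sub.min(axis=0).max())

    clusters: dict[str, list[str]] = {}
    for unit, ex in c.exemplar_of.items():
        clusters.setdefault(ex, []).append(unit)
    clusters = {e: sorted(m) for e, m in clusters.items()}
    dend = Dendrogram(leaves={e: list(m) for e, m in clusters.items()})
    active = dict(clusters)
    height = -np.inf
    merge_no = 0
    while len(active) > 1:
        best: tuple[float, str, str] | None = None
        for a, b in itertools.combinations(sorted(active), 2):
            score = joint_score(active[a] + active[b])
            if best is None or score > best[0]:
                best = (score, a, b)
        assert best is not None
        score, a, b = best
        height = max(height, -score)
        merge_no += 1
        new = f"merge{merge_no}"
        dend.merges.append((a, b, height, new))
        active[new] = sorted(active.pop(a) + active.pop(b))
    return dend


def tune_preference(
    s: SimilarityMatrix,
    target_k: int,
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_window: int = 100,
    seed: int = 0,
    max_evals: int = 50,
) -> tuple[ClusteringResult, bool]:
    """Search the preference for a desired cluster count.

    Starts from the bracket spanned by the minimum and maximum
    off-diagonal similarity (extended downward when even the minimum
    yields too many clusters), evaluates a coarse grid, and refines
    between evaluated preferences whose cluster counts straddle the
    target. The count is only roughly monotone in the preference, so an
    exact ``target_k`` plateau may not exist; in that case the clusters
    of the closest over-fragmented solution are agglomerated (exemplar-
    based merging) and the merge tree is cut at ``target_k`` — the
    standard recourse when affinity propagation alone will not settle on
    the desired count. Returns the clustering and a flag for whether
    ``target_k`` was attained.
    """
    n = s.n
    if not 1 <= target_k <= n:
        raise ClusteringError(f"target_k={target_k} outside [1, {n}]")

    def run(pref: float) -> ClusteringResult:
        return affinity_propagation(
            s,
            preference=pref,
            damping=damping,
            max_iter=max_iter,
            convergence_window=convergence_window,
            seed=seed,
        )

    off = s.off_diagonal()
    lo, hi = float(off.min()), float(off.max())
    span = max(hi - lo, 1e-6)
    evals = 0
    best: ClusteringResult | None = None
    seen: dict[float, int] = {}

    def consider(pref: float) -> ClusteringResult:
        nonlocal best, evals
        res = run(pref)
        evals += 1
        seen[pref] = res.n_clusters
        if best is None or abs(res.n_clusters - target_k) < abs(
            best.n_clusters - target_k
        ):
            best = res
        return res

    res_hi = consider(hi + 1e-9 * span)
    if res_hi.n_clusters == target_k:
        return res_hi, True
    res_lo = consider(lo)
    # the nominal bracket bottom may still over-fragment; push it down
    while res_lo.n_clusters > target_k and evals < max_evals // 3:
        lo -= span
        span *= 2
        res_lo = consider(lo)
    if res_lo.n_clusters == target_k:
        return res_lo, True
    # the count is only roughly monotone in the preference (plateaus and
    # local dips occur), so a coarse grid comes first and bisection then
    # refines between the closest straddling neighbors
    for pref in np.linspace(lo, hi, 14)[1:-1]:
        res = consider(float(pref))
        if res.n_clusters == target_k:
            return res, True
    while evals < max_evals:
        prefs = sorted(seen)
        straddles = [
            (p1, p2)
            for p1, p2 in zip(prefs, prefs[1:])
            if min(seen[p1], seen[p2]) < target_k < max(seen[p1], seen[p2])
            and p2 - p1 > 1e-12 * max(abs(p1), abs(p2), 1.0)
        ]
        if not straddles:
            break
        # prefer straddles whose counts tightly bracket the target (a
        # (k-1, k+1) gap is the most promising place for a k-plateau),
        # then wider ones: a plateau needs room to exist
        p1, p2 = min(
            straddles,
            key=lambda ab: (
                abs(seen[ab[0]] - target_k) + abs(seen[ab[1]] - target_k),
                -(ab[1] - ab[0]),
            ),
        )
        res = consider((p1 + p2) / 2.0)
        if res.n_clusters == target_k:
            return res, True
    assert best is not None
    # no preference hit the target exactly: agglomerate the closest
    # over-fragmented clustering and cut the merge tree at target_k
    over = [p for p, k in seen.items() if k > target_k]
    if over:
        base_pref = min(over, key=lambda p: (seen[p], p))
        base = run(base_pref)
        if base.n_clusters > target_k:
            dend = agglomerate_clusters(s, base)
            cut = dend.cut(target_k)
            merged = _exemplar_result_from_partition(s, cut, base)
            return merged, True
    return best, best.n_clusters == target_k


def _exemplar_result_from_partition(
    s: SimilarityMatrix, partition: dict[str, int], base: ClusteringResult
) -> ClusteringResult:
    """Rebuild an exemplar-based result from a unit -> cluster partition:
    each cluster's exemplar maximizes the summed similarity of its
    members, and the net similarity is recomputed accordingly."""
    ix = {lab: i for i, lab in enumerate(s.labels)}
    exemplar_of: dict[str, str] = {}
    for cid in set(partition.values()):
        members = [u for u, c in partition.items() if c == cid]
        rows = np.array([ix[u] for u in members])
        sub = s.values[np.ix_(rows, rows)].copy()
        np.fill_diagonal(sub, base.preference)
        ex = members[int(np.argmax(sub.sum(axis=0)))]
        for u in members:
            exemplar_of[u] = ex
    assign = np.array([ix[exemplar_of[u]] for u in s.labels])
    return ClusteringResult(
        labels=list(s.labels),
        exemplar_of=exemplar_of,
        preference=base.preference,
        net_similarity=net_similarity_of(s, assign, base.preference),
        converged=base.converged,
        iterations=base.iterations,
    )


def robustness_leave_genus_out(
    m: FeatureMatrix,
    drop: Sequence[str],
    target_k: Optional[int] = None,
    preference: Optional[float] = None,
    measure: str = "pearson",
    seed: int = 0,
) -> tuple[ClusteringResult, float]:
    """Re-cluster samples after removing whole genera; report the ARI.

    All rows whose genus component matches a dropped name are removed
    from the (raw or per-million) G or A matrix, columns are
    re-normalized to per-million, and the samples are re-clustered with
    the same parameters used for the full data. The adjusted Rand index
    compares the reduced clustering with the full one (1 = identical
    partitions). Exactly one of ``target_k`` / ``preference`` selects the
    clustering mode.
    """
    if (target_k is None) == (preference is None):
        raise ClusteringError("give exactly one of target_k or preference")
    genera = np.array(m.row_genera())
    missing = [g for g in drop if g not in set(genera)]
    if missing:
        raise ClusteringError(f"genera not present in matrix rows: {', '.join(missing)}")
    keep = ~np.isin(genera, list(drop))
    if not keep.any():
        raise ClusteringError("dropping the named genera removes all rows")

    def cluster(matrix: FeatureMatrix) -> ClusteringResult:
        norm = (
            matrix
            if matrix.normalization == "per_million"
            else normalize_per_million(matrix)
        )
        sim = similarity(norm, measure=measure)
        if target_k is not None:
            res, _exact = tune_preference(sim, target_k, seed=seed)
            return res
        return affinity_propagation(sim, preference=preference, seed=seed)

    full = cluster(m)
    reduced_raw = FeatureMatrix(
        role=m.role, data=m.data.loc[keep], normalization="raw"
    )
    try:
        reduced = cluster(reduced_raw)
    except MatrixError as exc:
        raise ClusteringError(f"re-normalization after drop failed: {exc}") from exc
    ari = adjusted_rand_score(full.cluster_labels, reduced.cluster_labels)
    return reduced, float(ari)
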
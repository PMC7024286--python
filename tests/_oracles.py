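"""Independent oracles used by the test suite.

Each function recomputes a quantity by a route deliberately different from the
package implementation: explicit per-column scans, exhaustive/optimal
assignment via the Hungarian algorithm, path-length recomputation on randomly
generated additive trees, and brute-force rank tables.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linear_sum_assignment

from cyanoprospect.specnet import FragmentSpectrum
from cyanoprospect.taxonomy import DistanceMatrix


def scan_p_distance(a: str, b: str) -> tuple[float, int]:
    """Explicit per-column p-distance scan (pairwise deletion)."""
    mism = n = 0
    for ca, cb in zip(a.upper(), b.upper()):
        if ca in "ACGT" and cb in "ACGT":
            n += 1
            mism += ca != cb
    return mism / n, n


def candidate_matrix(a, b, frag_tol: float, allow_shift: bool) -> np.ndarray:
    """Boolean matrix of peak pairs matchable directly or precursor-shifted."""
    delta = a.precursor_mz - b.precursor_mz
    diff = a.mz[:, None] - b.mz[None, :]
    cand = np.abs(diff) <= frag_tol
    if allow_shift and abs(delta) > frag_tol:
        cand |= np.abs(diff - delta) <= frag_tol
    return cand


def optimal_assignment_score(a, b, frag_tol: float, allow_shift: bool) -> float:
    """Maximum-weight one-to-one peak assignment (Hungarian; exact optimum)."""
    cand = candidate_matrix(a, b, frag_tol, allow_shift)
    weights = np.where(cand, a.intensity[:, None] * b.intensity[None, :], 0.0)
    rows, cols = linear_sum_assignment(weights, maximize=True)
    return float(weights[rows, cols].sum())


def is_conflict_free(a, b, frag_tol: float, allow_shift: bool) -> bool:
    """True when no peak has more than one candidate partner."""
    cand = candidate_matrix(a, b, frag_tol, allow_shift)
    return bool(cand.sum(axis=0).max(initial=0) <= 1
                and cand.sum(axis=1).max(initial=0) <= 1)


def random_spectrum(rng, n_peaks: int, feature_id: str = "q",
                    precursor_mz: float | None = None) -> FragmentSpectrum:
    """A random already-normalised spectrum for similarity tests."""
    if precursor_mz is None:
        precursor_mz = float(rng.uniform(300.0, 900.0))
    mz = np.sort(rng.uniform(50.0, precursor_mz - 20.0, size=n_peaks))
    intensity = rng.uniform(0.1, 1.0, size=n_peaks)
    intensity /= np.linalg.norm(intensity)
    return FragmentSpectrum(feature_id=feature_id, precursor_mz=precursor_mz,
                            mz=mz, intensity=intensity)


def random_additive_matrix(rng, n_taxa: int) -> tuple[DistanceMatrix, dict]:
    """Distance matrix of a random binary tree with positive branch lengths.

    Built by repeatedly joining two random subtrees; the returned dict maps
    each leaf pair to its exact tree path length (the additive ground truth).
    """
    ids = [f"t{i}" for i in range(n_taxa)]
    # each active node: dict leaf -> distance from leaf up to this node
    active = [{leaf: 0.0} for leaf in ids]
    paths: dict[frozenset, float] = {}
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        u, v = active[int(i)], active[int(j)]
        lu, lv = rng.uniform(0.05, 2.0, size=2)
        for leaf_u, du in u.items():
            for leaf_v, dv in v.items():
                paths[frozenset((leaf_u, leaf_v))] = du + lu + dv + lv
        merged = {leaf: d + lu for leaf, d in u.items()}
        merged.update({leaf: d + lv for leaf, d in v.items()})
        active = [node for k, node in enumerate(active) if k not in (int(i), int(j))]
        active.append(merged)
    d = np.zeros((n_taxa, n_taxa))
    for (i, a), (j, b) in itertools.combinations(enumerate(ids), 2):
        d[i, j] = d[j, i] = paths[frozenset((a, b))]
    scale = d.max()
    d /= scale  # DistanceMatrix requires [0, 1]
    paths = {pair: length / scale for pair, length in paths.items()}
    return DistanceMatrix(ids, d, np.ones_like(d, dtype=int)), paths


def brute_force_mutual_topk(edges, k: int) -> set:
    """Edge keys surviving mutual top-k pruning, from a full rank table."""
    ranked: dict[str, list] = {}
    for e in edges:
        ranked.setdefault(e.u, []).append(e)
        ranked.setdefault(e.v, []).append(e)
    top: dict[str, set] = {}
    for node, incident in ranked.items():
        other = lambda e: e.v if e.u == node else e.u
        incident = sorted(incident, key=lambda e: (-e.score, other(e)))
        top[node] = {other(e) for e in incident[:k]}
    return {e.key for e in edges if e.v in top[e.u] and e.u in top[e.v]}
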
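"""Feature-based molecular networking of MS/MS fragment spectra.

Spectra (one per LC-MS feature, from an MGF file plus a feature-quantification
table) are compared all-against-all with the *modified cosine*: fragment peaks
may match either directly or offset by the difference between the two
precursor masses, so that structural analogs differing by a single
modification still score highly. Edges are kept when the cosine exceeds a
threshold with enough matched peaks, pruned to mutual top-K neighbours, and
the connected components of two or more nodes form the molecular families
("clusters") of the network.

Annotation is a spectral-library search in two modes: *strict* (precursor
masses must agree within tolerance — classical dereplication) and *analog*
(precursor masses differ by up to ``max_delta`` Da; the difference is reported
as the putative modification mass).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentSpectrum",
    "SpectralEdge",
    "MolecularNetwork",
    "AnnotationHit",
    "GenusIntensityProfile",
    "NetworkParams",
    "read_mgf",
    "write_mgf",
    "read_quant",
    "attach_quant",
    "preprocess",
    "modified_cosine",
    "candidate_edges",
    "topk_mutual_filter",
    "build_network",
    "library_search",
    "analog_search",
    "genus_intensity",
    "export_graphml",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class FragmentSpectrum:
    """One MS/MS spectrum of one LC-MS feature.

    ``mz``/``intensity`` are parallel arrays sorted by ascending m/z with
    duplicate m/z values merged (intensities summed). ``sample_intensities``
    maps sample id to the precursor ion intensity of this feature in that
    sample (from the feature-quantification table).
    """

    feature_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    charge: int = 1
    rt: float = 0.0  # minutes
    sample_intensities: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size != self.intensity.size:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size == 0:
            raise ValueError(f"spectrum {self.feature_id!r} has no peaks")
        if self.precursor_mz <= 0:
            raise ValueError(f"spectrum {self.feature_id!r}: precursor m/z must be > 0")
        if np.any(self.mz <= 0) or np.any(self.intensity <= 0):
            raise ValueError(f"spectrum {self.feature_id!r}: peaks must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz, self.intensity = self.mz[order], self.intensity[order]
        if np.any(np.diff(self.mz) == 0):  # merge duplicate m/z
            uniq, inverse = np.unique(self.mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, self.intensity)
            self.mz, self.intensity = uniq, summed

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass(frozen=True)
class SpectralEdge:
    """An undirected similarity edge between two network nodes."""

    u: str
    v: str
    score: float
    n_matched: int
    precursor_delta: float

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError("self-edges are not allowed")
        if not 0.0 <= self.score <= 1.0 + 1e-9:
            raise ValueError(f"cosine score out of range: {self.score}")

    @property
    def key(self) -> frozenset:
        return frozenset((self.u, self.v))


@dataclass
class MolecularNetwork:
    """Nodes, retained edges and connected components of the network.

    ``clusters`` are the connected components with two or more nodes, sorted by
    decreasing size then smallest member id; every other node is a singleton.
    """

    spectra: dict
    edges: list
    clusters: list = field(default_factory=list)
    singletons: set = field(default_factory=set)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.spectra)
        for e in self.edges:
            g.add_edge(e.u, e.v, score=e.score, n_matched=e.n_matched,
                       precursor_delta=e.precursor_delta)
        return g

    def cluster_of(self) -> dict:
        """Node id -> 1-based cluster index (0 for singletons)."""
        out = {node: 0 for node in self.spectra}
        for idx, cluster in enumerate(self.clusters, start=1):
            for node in cluster:
                out[node] = idx
        return out

    def summary(self) -> dict:
        return {
            "n_features": len(self.spectra),
            "n_edges": len(self.edges),
            "n_clusters": len(self.clusters),
            "n_singletons": len(self.singletons),
        }


@dataclass(frozen=True)
class AnnotationHit:
    """A spectral-library match for one feature."""

    feature_id: str
    library_name: str
    score: float
    n_matched: int
    precursor_delta: float
    match_type: str  # "strict" | "analog"


@dataclass
class GenusIntensityProfile:
    """Per-node mean precursor intensity by cyanobacterial genus.

    ``frame`` is indexed by feature id with one column per genus; the dominant
    genus is the argmax (lexicographically first on ties, which are flagged in
    ``ties``).
    """

    frame: pd.DataFrame
    dominant: dict
    ties: set = field(default_factory=set)


@dataclass
class NetworkParams:
    """All tunables of the networking stage with their defaults.

    Cosine threshold 0.7, more-than-six matched peaks (>= 7) and mutual top-10
    pruning are the network edge rules; fragment/precursor tolerances of
    0.02 Da suit high-resolution Q-ToF data. Peaks within ``precursor_window``
    Da of the precursor are removed and intensities are square-root scaled then
    L2-normalised before scoring; ``max_peaks`` caps each spectrum at its most
    intense peaks to bound the all-pairs cost.
    """

    score_min: float = 0.7
    min_matched: int = 7
    topk: int = 10
    frag_tol: float = 0.02
    precursor_tol: float = 0.02
    allow_shift: bool = True
    precursor_window: float = 17.0
    intensity_scale: str = "sqrt"
    max_peaks: int = 100
    library_score_min: float = 0.7
    library_min_matched: int = 6
    analog_max_delta: float = 100.0


# ---------------------------------------------------------------------------
# I/O


def read_mgf(path) -> list[FragmentSpectrum]:
    """Read an MGF file (feature-based-networking dialect).

    Each BEGIN IONS block must carry PEPMASS; the feature id is taken from
    FEATURE_ID, then SCANS, and synthesised from the block index (with a
    warning) when both are absent. RTINSECONDS is converted to minutes.
    """
    spectra = []
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        block = 0
        while True:
            block += 1
            try:
                entry = next(reader)
            except StopIteration:
                break
            except Exception as exc:  # pyteomics parse failure
                raise ValueError(f"malformed MGF block {block} in {path}: {exc}") from exc
            params = entry["params"]
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"MGF block {block} in {path} lacks PEPMASS")
            fid = params.get("feature_id") or params.get("scans")
            if fid is None:
                fid = f"feature_{block}"
                logger.warning("MGF block %d lacks FEATURE_ID/SCANS; using %r", block, fid)
            charge = params.get("charge")
            charge = int(charge[0]) if charge else 1
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            spectra.append(
                FragmentSpectrum(
                    feature_id=str(fid),
                    precursor_mz=float(params["pepmass"][0]),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    charge=charge,
                    rt=rt,
                )
            )
    return spectra


def write_mgf(spectra, path, names: dict | None = None) -> None:
    """Write spectra as MGF; ``names`` adds a NAME field (library records)."""
    entries = []
    for s in spectra:
        params = {
            "pepmass": (round(s.precursor_mz, 6),),
            "charge": [s.charge],
            "rtinseconds": round(s.rt * 60.0, 6),
            "feature_id": s.feature_id,
        }
        if names and s.feature_id in names:
            params["name"] = names[s.feature_id]
        entries.append({
            "params": params,
            "m/z array": np.round(s.mz, 6),
            "intensity array": np.round(s.intensity, 6),
        })
    with open(str(path), "w") as fh:
        _mgf.write(entries, fh)


def read_quant(path) -> pd.DataFrame:
    """Feature-quantification CSV: rows = feature_id, columns = sample ids."""
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    return frame


def attach_quant(spectra, quant: pd.DataFrame) -> list[FragmentSpectrum]:
    """Attach per-sample precursor intensities from a quantification table."""
    out = []
    for s in spectra:
        if s.feature_id in quant.index:
            row = quant.loc[s.feature_id]
            s = replace(s, sample_intensities={c: float(row[c]) for c in quant.columns})
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# similarity


def preprocess(
    spec: FragmentSpectrum,
    precursor_window: float = 17.0,
    intensity_scale: str = "sqrt",
    max_peaks: int = 100,
) -> FragmentSpectrum | None:
    """Prepare a spectrum for cosine scoring; ``None`` marks an emptied spectrum.

    Removes fragment peaks within ``precursor_window`` Da of the precursor
    (precursor and its isotopes/losses would otherwise dominate every score),
    keeps the ``max_peaks`` most intense peaks, applies the intensity scaling
    and L2-normalises so the self-cosine is 1.
    """
    if intensity_scale not in ("sqrt", "none"):
        raise ValueError(f"unknown intensity scale {intensity_scale!r}")
    keep = np.abs(spec.mz - spec.precursor_mz) > precursor_window
    mz, intensity = spec.mz[keep], spec.intensity[keep]
    if mz.size == 0:
        return None
    if mz.size > max_peaks:
        top = np.sort(np.argsort(intensity, kind="stable")[-max_peaks:])
        mz, intensity = mz[top], intensity[top]
    if intensity_scale == "sqrt":
        intensity = np.sqrt(intensity)
    intensity = intensity / np.linalg.norm(intensity)
    return replace(spec, mz=mz, intensity=intensity)


def modified_cosine(
    a: FragmentSpectrum,
    b: FragmentSpectrum,
    frag_tol: float = 0.02,
    allow_shift: bool = True,
) -> tuple[float, int]:
    """Modified-cosine similarity between two preprocessed spectra.

    Peak pairs may match directly (|mz_a - mz_b| <= frag_tol) or, when
    ``allow_shift``, offset by the precursor mass difference. A greedy
    one-to-one assignment in decreasing intensity-product order (ties: smaller
    residual, then smaller mz_a + mz_b) gives the score as the sum of matched
    intensity products; with L2-normalised intensities it lies in [0, 1] and is
    symmetric in the two spectra.
    """
    if frag_tol <= 0:
        raise ValueError("frag_tol must be > 0")
    delta = a.precursor_mz - b.precursor_mz
    diff = a.mz[:, None] - b.mz[None, :]
    cand = np.abs(diff) <= frag_tol
    if allow_shift and abs(delta) > frag_tol:
        cand |= np.abs(diff - delta) <= frag_tol
    ii, jj = np.nonzero(cand)
    if ii.size == 0:
        return 0.0, 0
    prod = a.intensity[ii] * b.intensity[jj]
    resid = np.minimum(np.abs(diff[ii, jj]), np.abs(diff[ii, jj] - delta))
    mzsum = a.mz[ii] + b.mz[jj]
    order = np.lexsort((mzsum, resid, -prod))
    used_a = np.zeros(a.n_peaks, dtype=bool)
    used_b = np.zeros(b.n_peaks, dtype=bool)
    score = 0.0
    n_matched = 0
    for k in order:
        i, j = ii[k], jj[k]
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        score += prod[k]
        n_matched += 1
    return float(min(score, 1.0)), n_matched


# ---------------------------------------------------------------------------
# network construction


def candidate_edges(
    spectra,
    score_min: float = 0.7,
    min_matched: int = 7,
    frag_tol: float = 0.02,
    allow_shift: bool = True,
) -> list[SpectralEdge]:
    """Score all spectrum pairs; keep score > score_min and enough matched peaks.

    Spectra must already be preprocessed. The matched-peak floor defaults to 7
    ("more than six matched peaks").
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to build edges")
    edges = []
    for i, a in enumerate(spectra):
        for b in spectra[i + 1 :]:
            score, n = modified_cosine(a, b, frag_tol=frag_tol, allow_shift=allow_shift)
            if score > score_min and n >= min_matched:
                edges.append(SpectralEdge(a.feature_id, b.feature_id, score, n,
                                          a.precursor_mz - b.precursor_mz))
    return edges


def topk_mutual_filter(edges, k: int = 10) -> list[SpectralEdge]:
    """Keep edge (u, v) only if each node is within the other's k best neighbours.

    Neighbours are ranked by descending score; ties are broken by neighbour id
    so the filter is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    neighbours: dict[str, list] = {}
    for e in edges:
        neighbours.setdefault(e.u, []).append((-e.score, e.v))
        neighbours.setdefault(e.v, []).append((-e.score, e.u))
    topk = {
        node: {v for _, v in sorted(pairs)[:k]}
        for node, pairs in neighbours.items()
    }
    return [e for e in edges if e.v in topk[e.u] and e.u in topk[e.v]]


def build_network(spectra, params: NetworkParams | None = None) -> MolecularNetwork:
    """Full networking pipeline: preprocess, score, prune, find components."""
    params = params or NetworkParams()
    processed = []
    for s in spectra:
        p = preprocess(s, params.precursor_window, params.intensity_scale, params.max_peaks)
        if p is None:
            logger.warning("feature %s emptied by preprocessing; excluded", s.feature_id)
        else:
            processed.append(p)
    edges = candidate_edges(
        processed,
        score_min=params.score_min,
        min_matched=params.min_matched,
        frag_tol=params.frag_tol,
        allow_shift=params.allow_shift,
    )
    edges = topk_mutual_filter(edges, k=params.topk)

    g = nx.Graph()
    g.add_nodes_from(s.feature_id for s in processed)
    g.add_edges_from((e.u, e.v) for e in edges)
    components = [set(c) for c in nx.connected_components(g)]
    clusters = sorted(
        (c for c in components if len(c) >= 2), key=lambda c: (-len(c), min(c))
    )
    singletons = {node for c in components if len(c) == 1 for node in c}
    return MolecularNetwork(
        spectra={s.feature_id: s for s in spectra if g.has_node(s.feature_id)},
        edges=edges,
        clusters=clusters,
        singletons=singletons,
    )


# ---------------------------------------------------------------------------
# library annotation


def _search(spectra, library, score_min, min_matched, params, analog, max_delta):
    params = params or NetworkParams()
    prep = lambda s: preprocess(s, params.precursor_window, params.intensity_scale,
                                params.max_peaks)
    lib = [(name, prep(rec)) for name, rec in library]
    lib = [(name, rec) for name, rec in lib if rec is not None]
    if not lib:
        raise ValueError("library is empty after preprocessing")
    hits = []
    for raw in spectra:
        query = prep(raw)
        if query is None:
            continue
        best = None
        for name, rec in lib:
            delta = query.precursor_mz - rec.precursor_mz
            if analog:
                if not (params.precursor_tol < abs(delta) <= max_delta):
                    continue
            elif abs(delta) > params.precursor_tol:
                continue
            score, n = modified_cosine(query, rec, frag_tol=params.frag_tol,
                                       allow_shift=analog)
            if score > score_min and n >= min_matched:
                hit = AnnotationHit(raw.feature_id, name, score, n, delta,
                                    "analog" if analog else "strict")
                if best is None or (hit.score, -abs(hit.precursor_delta)) > (
                    best.score, -abs(best.precursor_delta)
                ):
                    best = hit
        if best is not None:
            hits.append(best)
    return hits


def library_search(
    spectra,
    library,
    score_min: float = 0.7,
    min_matched: int = 6,
    precursor_tol: float = 0.02,
    params: NetworkParams | None = None,
) -> list[AnnotationHit]:
    """Strict dereplication: precursor masses must agree within tolerance.

    Returns the best-scoring hit per feature with score > score_min and at
    least ``min_matched`` matched peaks (no shifted matching).
    """
    params = params or NetworkParams()
    params = replace(params, precursor_tol=precursor_tol)
    return _search(spectra, library, score_min, min_matched, params,
                   analog=False, max_delta=0.0)


def analog_search(
    spectra,
    library,
    score_min: float = 0.7,
    min_matched: int = 6,
    max_delta: float = 100.0,
    params: NetworkParams | None = None,
) -> list[AnnotationHit]:
    """Analog ("variable") dereplication: shift-aware match to modified variants.

    A hit requires 0 < |precursor delta| <= max_delta; the delta is reported as
    the putative modification mass. Features with a strict (delta ~ 0) match to
    a record are not analog hits of that record.
    """
    if max_delta <= 0:
        raise ValueError("max_delta must be > 0")
    return _search(spectra, library, score_min, min_matched, params,
                   analog=True, max_delta=max_delta)


# ---------------------------------------------------------------------------
# genus mapping and export


def genus_intensity(network: MolecularNetwork, sample_to_genus: dict) -> GenusIntensityProfile:
    """Mean precursor ion intensity per genus for every network node.

    For each node and genus, the arithmetic mean of the node's precursor
    intensities over all samples of that genus (a sample where the feature is
    absent contributes 0). The dominant genus is the argmax, lexicographically
    first on ties (flagged).
    """
    genera = sorted(set(sample_to_genus.values()))
    samples_by_genus = {
        g: [s for s, gg in sample_to_genus.items() if gg == g] for g in genera
    }
    unmapped = set()
    for spec in network.spectra.values():
        unmapped |= set(spec.sample_intensities) - set(sample_to_genus)
    if unmapped:
        raise ValueError(f"samples without a genus mapping: {sorted(unmapped)}")

    rows, dominant, ties = {}, {}, set()
    for fid, spec in network.spectra.items():
        means = {
            g: float(np.mean([spec.sample_intensities.get(s, 0.0)
                              for s in samples_by_genus[g]]))
            for g in genera
        }
        rows[fid] = means
        best = max(means.values())
        winners = sorted(g for g, m in means.items() if m == best)
        dominant[fid] = winners[0]
        if len(winners) > 1:
            ties.add(fid)
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=genera)
    return GenusIntensityProfile(frame, dominant, ties)


def export_graphml(
    network: MolecularNetwork,
    path,
    profile: GenusIntensityProfile | None = None,
    hits=None,
) -> None:
    """Write the network as GraphML with node/edge attributes for Cytoscape-style viewing."""
    g = nx.Graph()
    cluster_of = network.cluster_of()
    hit_by_feature = {h.feature_id: h for h in (hits or [])}
    for fid, spec in network.spectra.items():
        attrs = {
            "feature_id": fid,
            "precursor_mz": float(spec.precursor_mz),
            "rt": float(spec.rt),
            "cluster": int(cluster_of[fid]),
        }
        if profile is not None and fid in profile.frame.index:
            for genus in profile.frame.columns:
                attrs[f"mean_intensity_{genus}"] = float(profile.frame.at[fid, genus])
            attrs["dominant_genus"] = profile.dominant[fid]
        hit = hit_by_feature.get(fid)
        if hit is not None:
            attrs["annotation_name"] = hit.library_name
            attrs["annotation_type"] = hit.match_type
            attrs["annotation_score"] = float(hit.score)
        g.add_node(fid, **attrs)
    for e in network.edges:
        g.add_edge(e.u, e.v, score=float(e.score), n_matched=int(e.n_matched),
                   precursor_delta=float(e.precursor_delta))
    nx.write_graphml(g, str(path))
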
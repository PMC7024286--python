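"""16S rRNA distance-based taxon delimitation.

Implements the distance stage of a polyphasic-free, sequence-only strain
identification workflow: uncorrected pairwise p-distances on a fixed multiple
alignment, a bootstrap-supported neighbor-joining tree, monophyly checks, and
assignment of strains to hypothetical species (99% identity cutoff) and genera
(95% cutoff) relative to a set of named reference sequences.

Distances are *dissimilarity fractions*: 0.01 dissimilarity == 99% identity.
Columns where either sequence carries a gap or an ambiguity code are excluded
pair by pair (pairwise deletion).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import TreeNode
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

__all__ = [
    "AlignedSequences",
    "DistanceMatrix",
    "PhyloTree",
    "TaxonDelimitation",
    "p_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "is_monophyletic",
    "delimit",
    "SPECIES_CUTOFF",
    "GENUS_CUTOFF",
]

#: Dissimilarity at or below which two strains are conspecific (99% identity).
SPECIES_CUTOFF = 0.01
#: Dissimilarity at or below which two strains are congeneric (95% identity).
GENUS_CUTOFF = 0.05

_UNAMBIGUOUS = frozenset(b"ACGT")


# ---------------------------------------------------------------------------
# containers


@dataclass
class AlignedSequences:
    """A fixed multiple alignment of nucleotide sequences.

    ``records`` is an ordered list of ``(id, sequence)`` pairs. Sequences may
    contain gaps (``-``), ``N`` and IUPAC ambiguity codes; every sequence must
    have the same length and ids must be unique and non-empty.
    """

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids) or any(not rid for rid in ids):
            raise ValueError("sequence ids must be unique and non-empty")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(
                f"aligned sequences must have equal lengths, got {sorted(lengths)}"
            )

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def trim(self, start: int, stop: int) -> "AlignedSequences":
        """Restrict the alignment to columns ``[start, stop)``."""
        return AlignedSequences([(rid, seq[start:stop]) for rid, seq in self.records])

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Encode as (chars, valid): uint8 character matrix and an A/C/G/T mask."""
        chars = np.frombuffer(
            "".join(seq.upper() for _, seq in self.records).encode("ascii"),
            dtype=np.uint8,
        ).reshape(len(self.records), self.length)
        valid = (
            (chars == ord("A"))
            | (chars == ord("C"))
            | (chars == ord("G"))
            | (chars == ord("T"))
        )
        return chars, valid

    @classmethod
    def from_fasta(cls, path, trim: tuple[int, int] | None = None) -> "AlignedSequences":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        aln = cls(records)
        return aln.trim(*trim) if trim else aln

    def to_fasta(self, path) -> None:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in self.records),
            str(path),
            "fasta",
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix with per-pair site counts."""

    ids: list[str]
    d: np.ndarray
    n_sites: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.n_sites = np.asarray(self.n_sites)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any((self.d < 0) | (self.d > 1)):
            raise ValueError("p-distances must lie in [0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        frame = pd.read_csv(path, index_col=0)
        d = frame.to_numpy(dtype=float)
        d = (d + d.T) / 2.0  # symmetrize round-tripped values
        np.fill_diagonal(d, 0.0)
        return cls(list(frame.index), d, np.zeros_like(d, dtype=int))


class PhyloTree:
    """A rooted tree over strain/reference ids, with optional clade supports.

    Thin wrapper around :class:`skbio.TreeNode` exposing the few operations the
    delimitation workflow needs. Supports are percentages in [0, 100] keyed by
    the frozenset of leaf names under each internal node.
    """

    def __init__(self, tree: TreeNode, supports: dict[frozenset, float] | None = None):
        self.tree = tree
        self.supports = supports or {}
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("leaf labels must be unique")
        if any(not (0 <= s <= 100) for s in self.supports.values()):
            raise ValueError("supports must lie in [0, 100]")

    def leaf_names(self) -> list[str]:
        return [tip.name for tip in self.tree.tips()]

    def clades(self) -> set[frozenset]:
        """Leaf sets of all internal nodes below the root."""
        out = set()
        for node in self.tree.non_tips(include_self=False):
            out.add(frozenset(tip.name for tip in node.tips()))
        return out

    def path_length(self, a: str, b: str) -> float:
        return float(self.tree.find(a).distance(self.tree.find(b)))

    def to_newick(self, path=None) -> str | None:
        tree = self.tree.copy()
        for node in tree.non_tips(include_self=False):
            clade = frozenset(tip.name for tip in node.tips())
            if clade in self.supports:
                node.name = f"{self.supports[clade]:g}"
        buf = io.StringIO()
        tree.write(buf, format="newick")
        text = buf.getvalue()
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        tree = TreeNode.read(source, format="newick")
        supports: dict[frozenset, float] = {}
        for node in tree.non_tips(include_self=False):
            if node.name:
                try:
                    value = float(node.name)
                except ValueError:
                    continue
                if 0 <= value <= 100:
                    supports[frozenset(tip.name for tip in node.tips())] = value
        return cls(tree, supports)


# ---------------------------------------------------------------------------
# distances


def p_distance(a: str, b: str, gap_policy: str = "pairwise-deletion") -> tuple[float, int]:
    """Uncorrected distance between two aligned sequences.

    Returns ``(dissimilarity, n_compared)`` where dissimilarity is the fraction
    of mismatching sites among columns where *both* characters are unambiguous
    bases (A/C/G/T). Gap and ambiguity columns are excluded pairwise.
    """
    if gap_policy != "pairwise-deletion":
        raise ValueError(f"unsupported gap policy: {gap_policy!r}")
    if len(a) != len(b):
        raise ValueError(f"sequences have unequal lengths ({len(a)} vs {len(b)})")
    aln = AlignedSequences.__new__(AlignedSequences)
    aln.records = [("a", a), ("b", b)]
    chars, valid = AlignedSequences.to_arrays(aln)
    mask = valid[0] & valid[1]
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no comparable sites: sequences do not overlap")
    mismatches = int(((chars[0] != chars[1]) & mask).sum())
    return mismatches / n, n


def _pairwise_p(chars: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs p-distance on encoded alignment arrays (vectorized)."""
    n = chars.shape[0]
    d = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        mask = valid[i] & valid[i + 1 :]
        ns = mask.sum(axis=1)
        mism = ((chars[i] != chars[i + 1 :]) & mask).sum(axis=1)
        counts[i, i + 1 :] = ns
        counts[i + 1 :, i] = ns
        with np.errstate(invalid="ignore"):
            frac = np.where(ns > 0, mism / np.maximum(ns, 1), np.nan)
        d[i, i + 1 :] = frac
        d[i + 1 :, i] = frac
    return d, counts


def distance_matrix(aln: AlignedSequences) -> DistanceMatrix:
    """Pairwise p-distance matrix over all sequences of an alignment."""
    chars, valid = aln.to_arrays()
    d, counts = _pairwise_p(chars, valid)
    bad = np.argwhere(np.triu(counts == 0, k=1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
        )
    return DistanceMatrix(aln.ids, d, counts)


# ---------------------------------------------------------------------------
# trees


def neighbor_joining(D: DistanceMatrix, outgroup: str) -> PhyloTree:
    """Neighbor-joining tree rooted on the branch leading to ``outgroup``.

    Negative branch lengths produced by NJ on non-additive data are clamped to
    zero. On an additive matrix the leaf-to-leaf path lengths of the result
    reproduce the input distances.
    """
    if outgroup not in D.ids:
        raise ValueError(f"outgroup {outgroup!r} is not among the matrix ids")
    if len(D.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    unrooted = _skbio_nj(_SkbioDM(D.d, D.ids), neg_as_zero=True)
    rooted = unrooted.root_at(unrooted.find(outgroup), above=True)
    return PhyloTree(rooted)


def bootstrap_support(
    aln: AlignedSequences,
    n_reps: int = 100,
    seed: int = 0,
    outgroup: str | None = None,
) -> PhyloTree:
    """NJ tree on the full alignment with column-bootstrap clade supports.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each clade of the full-data tree is the percentage of replicate
    trees (rooted on the same outgroup) containing that clade. Deterministic
    for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if outgroup is None:
        outgroup = aln.ids[0]
    full = neighbor_joining(distance_matrix(aln), outgroup)
    clades = full.clades()
    hits = {clade: 0 for clade in clades}
    chars, valid = aln.to_arrays()
    rng = np.random.default_rng(seed)
    length = aln.length
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        d, counts = _pairwise_p(chars[:, cols], valid[:, cols])
        if np.any(np.triu(counts == 0, k=1)):
            continue  # degenerate resample: no overlap for some pair
        rep = neighbor_joining(DistanceMatrix(aln.ids, d, counts), outgroup)
        rep_clades = rep.clades()
        for clade in clades & rep_clades:
            hits[clade] += 1
    supports = {clade: 100.0 * k / n_reps for clade, k in hits.items()}
    return PhyloTree(full.tree, supports)


def is_monophyletic(tree: PhyloTree, leafset) -> bool:
    """True iff ``leafset`` is exactly the leaf set of some subtree."""
    leafset = frozenset(leafset)
    names = set(tree.leaf_names())
    unknown = leafset - names
    if unknown:
        raise ValueError(f"ids not in tree: {sorted(unknown)}")
    if len(leafset) <= 1 or leafset == names:
        return True
    return leafset in tree.clades()


# ---------------------------------------------------------------------------
# delimitation


@dataclass
class TaxonDelimitation:
    """Species/genus assignment of every id in a distance matrix.

    ``frame`` is indexed by id with columns ``species_cluster``,
    ``genus_cluster``, ``nearest_reference``, ``nearest_reference_dissimilarity``,
    ``new_species``, ``new_genus`` and ``monophyly_ok``.
    """

    frame: pd.DataFrame
    species_cutoff: float = SPECIES_CUTOFF
    genus_cutoff: float = GENUS_CUTOFF

    @property
    def n_species(self) -> int:
        return int(self.frame["species_cluster"].nunique())

    @property
    def n_genera(self) -> int:
        return int(self.frame["genus_cluster"].nunique())

    def to_report(self) -> pd.DataFrame:
        """Table-1-style report: one row per strain with percent similarity."""
        rep = self.frame.copy()
        rep.insert(0, "strain", rep.index)
        sim = 100.0 * (1.0 - rep.pop("nearest_reference_dissimilarity"))
        rep["percent_similarity_to_nearest_reference"] = sim.round(2)
        rep["affiliation"] = np.where(
            rep.pop("new_genus"),
            "new genus, new species",
            np.where(rep.pop("new_species"), "known genus, new species", "known species"),
        )
        return rep.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_report().to_csv(path, index=False)


def _single_linkage_labels(d: np.ndarray, ids: list[str], cutoff: float) -> dict[str, int]:
    """Single-linkage components at dissimilarity <= cutoff, canonically labelled.

    Labels are assigned by the lexicographically smallest member id of each
    cluster so the result does not depend on input ordering.
    """
    raw = fcluster(linkage(squareform(d, checks=False), method="single"),
                   t=cutoff, criterion="distance")
    members: dict[int, list[str]] = {}
    for rid, lab in zip(ids, raw):
        members.setdefault(int(lab), []).append(rid)
    order = sorted(members.values(), key=min)
    labels: dict[str, int] = {}
    for k, group in enumerate(order, start=1):
        for rid in group:
            labels[rid] = k
    return labels


def delimit(
    D: DistanceMatrix,
    tree: PhyloTree,
    reference_ids=(),
    species_cutoff: float = SPECIES_CUTOFF,
    genus_cutoff: float = GENUS_CUTOFF,
) -> TaxonDelimitation:
    """Assign every id to a hypothetical species and genus.

    Species clusters are single-linkage components at dissimilarity <=
    ``species_cutoff`` (99% identity), genus clusters at <= ``genus_cutoff``
    (95%). A strain is a *new species* if no reference lies within the species
    cutoff, a *new genus* if none lies within the genus cutoff. Each species
    cluster is additionally checked for monophyly on ``tree``; clusters chained
    together across the cutoff are flagged (``monophyly_ok=False``), not split.
    """
    for name, cutoff in (("species_cutoff", species_cutoff), ("genus_cutoff", genus_cutoff)):
        if not 0 < cutoff < 1:
            raise ValueError(f"{name} must lie strictly between 0 and 1, got {cutoff}")
    if species_cutoff > genus_cutoff:
        raise ValueError("species_cutoff must not exceed genus_cutoff")
    reference_ids = set(reference_ids)
    unknown = reference_ids - set(D.ids)
    if unknown:
        raise ValueError(f"reference ids not in matrix: {sorted(unknown)}")
    missing = set(D.ids) - set(tree.leaf_names())
    if missing:
        raise ValueError(f"matrix ids missing from tree: {sorted(missing)}")

    ids = D.ids
    species = _single_linkage_labels(D.d, ids, species_cutoff)
    genus = _single_linkage_labels(D.d, ids, genus_cutoff)

    ref_idx = [ids.index(r) for r in sorted(reference_ids)]
    rows = []
    for i, rid in enumerate(ids):
        others = [j for j in ref_idx if ids[j] != rid]
        if others:
            j = min(others, key=lambda j: (D.d[i, j], ids[j]))
            nearest, nearest_d = ids[j], float(D.d[i, j])
        else:
            nearest, nearest_d = None, np.nan
        if rid in reference_ids:
            new_sp = new_gen = False
        elif not others:
            new_sp = new_gen = True
        else:
            new_sp = nearest_d > species_cutoff
            new_gen = nearest_d > genus_cutoff
        rows.append((rid, species[rid], genus[rid], nearest, nearest_d, new_sp, new_gen))

    frame = pd.DataFrame(
        rows,
        columns=[
            "id",
            "species_cluster",
            "genus_cluster",
            "nearest_reference",
            "nearest_reference_dissimilarity",
            "new_species",
            "new_genus",
        ],
    ).set_index("id")

    mono = {}
    for label, group in frame.groupby("species_cluster"):
        mono[label] = is_monophyletic(tree, set(group.index))
    frame["monophyly_ok"] = frame["species_cluster"].map(mono)
    return TaxonDelimitation(frame, species_cutoff, genus_cutoff)
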
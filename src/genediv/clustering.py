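"""Phylotype definition by greedy identity clustering of protein sequences.

A *phylotype* is an operational cluster of protein sequences of one gene
family at (by default) >= 90% global amino-acid identity — roughly the level
of similarity seen between organisms of the same genus.  Clustering is
greedy and centroid-based in the CD-HIT style: sequences are visited in a
deterministic order and each either joins the first existing representative
it matches at the identity threshold or founds a new phylotype.

Identity is computed from a Needleman–Wunsch global alignment (BLOSUM62,
affine gaps) as identical aligned pairs divided by total alignment columns,
gap columns included in the denominator.  A shorter-sequence denominator is
available as an option.

A UPGMA tree over phylotype representatives (distance = 1 − identity) is
provided for ordering heatmap rows; it is a display device, not a
phylogenetic estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqRecord import SeqRecord
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InputError, ParameterError


@dataclass(frozen=True)
class ClusteringParams:
    """Scoring and ordering choices for phylotype clustering.

    Parameters
    ----------
    threshold : float
        Minimum global identity to a representative for cluster membership.
    matrix : str
        Substitution matrix name understood by Biopython.
    gap_open, gap_extend : float
        Affine gap scores (negative); applied to end gaps as well, so
        terminal gaps count against identity.
    ordering : {"length_desc", "abundance_desc"}
        Greedy visiting order; ties broken lexicographically by id.
    identity_denominator : {"columns", "shorter"}
        Divide identical pairs by all alignment columns (default) or by the
        shorter sequence length.
    """

    threshold: float = 0.90
    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    ordering: str = "length_desc"
    identity_denominator: str = "columns"

    def __post_init__(self):
        if not 0.0 < self.threshold <= 1.0:
            raise ParameterError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.ordering not in ("length_desc", "abundance_desc"):
            raise ParameterError(f"unknown ordering rule {self.ordering!r}")
        if self.identity_denominator not in ("columns", "shorter"):
            raise ParameterError(
                f"unknown identity denominator {self.identity_denominator!r}"
            )


DEFAULT_PARAMS = ClusteringParams()


@dataclass
class Phylotype:
    """One cluster of sequences; the representative is always a member."""

    phylotype_id: str
    family: str
    representative: str
    members: list[str] = field(default_factory=list)


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _validate_protein(seq: str, seq_id: str, alphabet: frozenset) -> None:
    if not seq:
        raise InputError(f"sequence {seq_id!r} is empty")
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise InputError(
                f"invalid residue {ch!r} at position {pos} of sequence {seq_id!r}"
            )


def global_align_identity(
    seq_a: str | SeqRecord,
    seq_b: str | SeqRecord,
    params: ClusteringParams = DEFAULT_PARAMS,
) -> float:
    """Global-alignment identity between two protein sequences, in [0, 1].

    Identity is identical aligned residue pairs divided by total alignment
    columns (gap columns included), or by the shorter sequence length when
    ``params.identity_denominator == "shorter"``.  Symmetric in its
    arguments.
    """
    id_a = getattr(seq_a, "id", "seq_a")
    id_b = getattr(seq_b, "id", "seq_b")
    a = str(getattr(seq_a, "seq", seq_a)).upper()
    b = str(getattr(seq_b, "seq", seq_b)).upper()
    aligner = _aligner(params.matrix, params.gap_open, params.gap_extend)
    alphabet = frozenset(str(aligner.substitution_matrix.alphabet))
    _validate_protein(a, id_a, alphabet)
    _validate_protein(b, id_b, alphabet)
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    if params.identity_denominator == "shorter":
        denom = min(len(a), len(b))
    else:
        denom = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / denom


def _greedy_order(
    records: Sequence[SeqRecord],
    params: ClusteringParams,
    abundance: Mapping[str, float] | None,
) -> list[SeqRecord]:
    if params.ordering == "abundance_desc":
        if abundance is None:
            raise ParameterError("abundance_desc ordering requires an abundance map")
        return sorted(records, key=lambda r: (-abundance.get(r.id, 0.0), r.id))
    return sorted(records, key=lambda r: (-len(r.seq), r.id))


def greedy_cluster(
    records: Sequence[SeqRecord],
    params: ClusteringParams = DEFAULT_PARAMS,
    family: str = "gene",
    abundance: Mapping[str, float] | None = None,
) -> list[Phylotype]:
    """Greedy centroid clustering of protein sequences at an identity threshold.

    Sequences are visited longest-first (or most-abundant-first), ties broken
    lexicographically by id; each sequence joins the first existing
    representative it matches at ``params.threshold``, else founds a new
    phylotype.  Deterministic for a given input set regardless of input
    order.
    """
    if not records:
        raise InputError("no sequences to cluster")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate sequence id(s): {', '.join(dup)}")

    ordered = _greedy_order(records, params, abundance)
    phylotypes: list[Phylotype] = []
    reps: list[SeqRecord] = []
    for rec in ordered:
        assigned = False
        for k, rep in enumerate(reps):
            if global_align_identity(rec, rep, params) >= params.threshold:
                phylotypes[k].members.append(rec.id)
                assigned = True
                break
        if not assigned:
            phylotypes.append(
                Phylotype(
                    phylotype_id=f"{family}_PT{len(phylotypes):03d}",
                    family=family,
                    representative=rec.id,
                    members=[rec.id],
                )
            )
            reps.append(rec)
    return phylotypes


def membership_map(phylotypes: Iterable[Phylotype]) -> dict[str, str]:
    """Flatten phylotypes to a sequence-id -> phylotype-id mapping."""
    out: dict[str, str] = {}
    for pt in phylotypes:
        for member in pt.members:
            out[member] = pt.phylotype_id
    return out


def _newick_from_tree(node, height_of, names) -> str:
    if node.is_leaf():
        return names[node.id]
    parts = []
    for child in (node.get_left(), node.get_right()):
        branch = (height_of(node) - height_of(child)) / 2.0
        parts.append(f"{_newick_from_tree(child, height_of, names)}:{branch:.10f}")
    return f"({','.join(parts)})"


def build_guide_tree(
    records: Sequence[SeqRecord],
    params: ClusteringParams = DEFAULT_PARAMS,
) -> str:
    """UPGMA guide tree (newick) over representatives, d = 1 − identity.

    Leaves are the record ids; the tree is ultrametric by construction and
    deterministic (ids are sorted before distances are computed, so ties in
    merge order resolve lexicographically).  With fewer than two records a
    single-leaf newick string is returned.
    """
    recs = sorted(records, key=lambda r: r.id)
    if len(recs) == 0:
        raise InputError("no representatives supplied")
    if len(recs) == 1:
        return f"{recs[0].id};"
    n = len(recs)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - global_align_identity(recs[i], recs[j], params)
            dmat[i, j] = dmat[j, i] = d
    linkage = hierarchy.linkage(squareform(dmat, checks=False), method="average")
    tree = hierarchy.to_tree(linkage)

    def height_of(node):
        return 0.0 if node.is_leaf() else node.dist

    names = [r.id for r in recs]
    return _newick_from_tree(tree, height_of, names) + ";"


def guide_tree_leaf_order(newick: str) -> list[str]:
    """Leaf ids in the left-to-right order of a newick string."""
    import re

    out: list[str] = []
    for token in re.split(r"[(),;]", newick):
        name = token.split(":")[0].strip()
        if name:
            out.append(name)
    return out
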
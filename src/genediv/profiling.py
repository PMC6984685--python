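"""Read recruitment and abundance normalisation.

Reads are recruited to known reference gene sequences by k-mer-seeded
banded nucleotide alignment (edlib, infix mode, both strands): each read is
assigned to at most one reference — the best-scoring hit passing the
identity and length thresholds, ties broken by lexicographically smallest
reference id.  Counts are converted to RPKM (reads per kilobase of gene
length per million reads), to per-capita gene abundance (gene RPKM over
summed single-copy-marker RPKM, an estimate of the fraction of individuals
carrying the gene), and to phylotype relative-abundance profiles (member
RPKMs summed per phylotype, each sample renormalised to 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .errors import EmptySampleError, InputError, ParameterError

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RecruitmentParams:
    """Thresholds and seeding for read recruitment.

    ``min_alignment_len_nt`` defaults to 0.8 x read length at recruit time.
    ``kmer_seed_len`` = 13 guarantees (by pigeonhole) an exact seed for a
    100 nt read with up to 6 mismatches; a handful of evenly spaced seed
    positions is tried first, falling back to every position and finally to
    exhaustive alignment against all references.
    """

    min_nucleotide_identity: float = 0.95
    min_alignment_len_nt: int | None = None
    kmer_seed_len: int = 13
    n_seed_positions: int = 8

    def __post_init__(self):
        if not 0 < self.min_nucleotide_identity <= 1:
            raise ParameterError("min_nucleotide_identity must be in (0, 1]")
        if self.kmer_seed_len < 4:
            raise ParameterError("kmer_seed_len must be >= 4")


class ReadRecruiter:
    """K-mer index over references plus banded alignment of queries."""

    def __init__(
        self,
        references: Sequence[SeqRecord],
        params: RecruitmentParams = RecruitmentParams(),
    ):
        if not references:
            raise InputError("references must be nonempty")
        ids = [r.id for r in references]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate reference ids")
        self.params = params
        self.ref_ids = ids
        self.ref_seqs = {r.id: str(r.seq).upper() for r in references}
        self.ref_lengths = pd.Series(
            {rid: len(seq) for rid, seq in self.ref_seqs.items()}, name="length_nt"
        )
        k = params.kmer_seed_len
        self._index: dict[str, set[str]] = {}
        for rid, seq in self.ref_seqs.items():
            for strand_seq in (seq, _revcomp(seq)):
                for i in range(len(strand_seq) - k + 1):
                    self._index.setdefault(strand_seq[i : i + k], set()).add(rid)

    def _candidates(self, read: str) -> set[str]:
        k = self.params.kmer_seed_len
        if len(read) < k:
            return set(self.ref_ids)
        positions = np.linspace(
            0, len(read) - k, num=min(self.params.n_seed_positions, len(read) - k + 1)
        ).astype(int)
        cands: set[str] = set()
        for pos in positions:
            cands |= self._index.get(read[pos : pos + k], set())
        if not cands:
            for pos in range(len(read) - k + 1):
                cands |= self._index.get(read[pos : pos + k], set())
        if not cands:
            cands = set(self.ref_ids)
        return cands

    def assign(self, read_seq: str) -> str | None:
        """Best reference id for one read, or None if unassigned."""
        read = read_seq.upper()
        p = self.params
        min_len = (
            p.min_alignment_len_nt
            if p.min_alignment_len_nt is not None
            else int(0.8 * len(read))
        )
        if len(read) < min_len:
            return None
        max_dist = int(np.floor((1.0 - p.min_nucleotide_identity) * len(read)))
        best: tuple[int, str] | None = None
        rc = _revcomp(read)
        for rid in sorted(self._candidates(read)):
            ref = self.ref_seqs[rid]
            dist = None
            for query in (read, rc):
                res = edlib.align(query, ref, mode="HW", task="distance", k=max_dist)
                d = res["editDistance"]
                if d >= 0 and (dist is None or d < dist):
                    dist = d
            if dist is None:
                continue
            if best is None or dist < best[0]:
                best = (dist, rid)
        return best[1] if best else None

    def recruit(
        self, reads: Iterable[SeqRecord | str]
    ) -> tuple[pd.Series, int]:
        """Per-reference read counts and the number of unassigned reads."""
        counts = {rid: 0 for rid in self.ref_ids}
        unassigned = 0
        n = 0
        for read in reads:
            n += 1
            seq = str(getattr(read, "seq", read))
            rid = self.assign(seq)
            if rid is None:
                unassigned += 1
            else:
                counts[rid] += 1
        if n == 0:
            warnings.warn("empty read set: all-zero counts")
        return pd.Series(counts, name="reads"), unassigned


def recruit_reads(
    reads: Iterable[SeqRecord | str],
    references: Sequence[SeqRecord],
    params: RecruitmentParams = RecruitmentParams(),
) -> tuple[pd.Series, int]:
    """One-shot recruitment; see :class:`ReadRecruiter`."""
    return ReadRecruiter(references, params).recruit(reads)


def rpkm(read_count: float, gene_len_nt: int, total_reads: int) -> float:
    """Reads per kilobase of gene length per million reads."""
    if gene_len_nt <= 0:
        raise ParameterError("gene_len_nt must be > 0")
    if total_reads <= 0:
        raise EmptySampleError("total_reads must be > 0 for RPKM")
    return read_count / (gene_len_nt / 1e3) / (total_reads / 1e6)


def rpkm_matrix(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, int] | pd.Series,
    total_reads: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """RPKM for a reference x sample count table.

    ``total_reads`` is the per-sample library size (all reads sequenced,
    assigned or not), keyed by the count table's column names.
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise InputError(f"missing gene length for: {missing}")
    totals = pd.Series(total_reads).reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise EmptySampleError("every sample needs a positive total read count")
    return counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


def per_capita_abundance(
    gene_rpkm: pd.DataFrame, marker_rpkm: pd.DataFrame
) -> pd.Series:
    """Fraction of individuals carrying the gene, per sample.

    Summed gene-family RPKM divided by summed single-copy marker RPKM (the
    marker sum pools all marker forms, e.g. bacterial plus archaeal).
    Samples with zero marker signal come back as NaN and should be excluded
    downstream.
    """
    gene_sum = gene_rpkm.sum(axis=0)
    marker_sum = marker_rpkm.sum(axis=0)
    zero = marker_sum <= 0
    if zero.any():
        warnings.warn(
            f"zero marker signal in sample(s) {list(marker_sum.index[zero])}; "
            "per-capita abundance undefined there"
        )
    out = gene_sum / marker_sum.where(~zero)
    out.name = "per_capita"
    return out


def sum_by_phylotype(
    matrix: pd.DataFrame, membership: Mapping[str, str]
) -> pd.DataFrame:
    """Sum member-sequence rows into phylotype rows."""
    missing = [rid for rid in matrix.index if rid not in membership]
    if missing:
        raise InputError(f"membership does not cover row id(s): {missing}")
    grouped = matrix.groupby([membership[rid] for rid in matrix.index]).sum()
    grouped.index.name = "phylotype_id"
    return grouped.sort_index()


def phylotype_relative_abundance(
    matrix: pd.DataFrame, membership: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Phylotype relative-abundance profiles from an RPKM matrix.

    Member rows are summed into phylotype rows (when a membership map is
    given), then each sample column is divided by its column sum.  Columns
    with zero total stay all-zero — "gene not observed" samples rather than
    an error.
    """
    pt = sum_by_phylotype(matrix, membership) if membership else matrix.copy()
    colsum = pt.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = pt.div(colsum.where(colsum > 0), axis=1)
    return rel.fillna(0.0)
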
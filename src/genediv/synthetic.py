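"""Synthetic functional-gene community generator.

Stands in for field metagenomes in tests and demonstrations: it plants a
known phylotype structure (protein + coding nucleotide sequences with
controlled within/between-phylotype identity), simulates phylotype
relative-abundance trajectories under named dynamical regimes, generates
environmental covariates with a mid-series hydrologic shift (surface-water
to groundwater transition), and emits per-sample single-end reads whose
depth tracks phylotype abundance.  A single-copy marker family (rplB
analog, one copy per simulated individual) anchors per-capita
normalisation.

Regimes map onto the qualitative dynamics seen for N-cycling gene
families: *resistant* (low random-walk step, stable profile, narG/nosZ
style), *resilient* (large step, phylotype turnover, nirKS/norB style) and
*low_richness* (few phylotypes, amoA/nxrA style).  The only dynamical dial
is ``walk_sigma``, the step size of a Gaussian random walk on
log-abundance: it maps monotonically onto the downstream turnover
statistic (mean temporal variance of phylotype relative abundance), and
``walk_sigma = 0`` gives exactly constant profiles.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from .clustering import DEFAULT_PARAMS, ClusteringParams, global_align_identity
from .errors import ParameterError
from .io import make_record

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Standard codon table, one entry per amino acid (synonymous codons listed
# so reverse translation can vary silently between genes).
CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}


@dataclass(frozen=True)
class RegimeParams:
    """Parameters of one abundance-dynamics regime.

    ``walk_sigma`` is the standard deviation of the per-step Gaussian
    increment on log-abundance (dimensionless); ``dominance_alpha`` is the
    Dirichlet concentration of the initial abundance draw (small values give
    one dominant phylotype).  A *resilient* regime must have strictly larger
    ``walk_sigma`` than any *resistant* regime it is paired with.
    """

    name: str
    n_phylotypes: int
    n_timepoints: int = 11
    walk_sigma: float = 0.1
    dominance_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_phylotypes < 1:
            raise ParameterError("n_phylotypes must be >= 1")
        if self.n_timepoints < 2:
            raise ParameterError("n_timepoints must be >= 2")
        if self.walk_sigma < 0:
            raise ParameterError("walk_sigma must be >= 0")
        if self.dominance_alpha <= 0:
            raise ParameterError("dominance_alpha must be > 0")


@dataclass
class PhylotypePool:
    """Planted sequences for one gene family, with ground-truth labels."""

    family: str
    proteins: list[SeqRecord]
    cds: list[SeqRecord]
    cluster_labels: dict[str, str]  # sequence id -> phylotype id

    @property
    def phylotype_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid in self.cluster_labels.values():
            seen.setdefault(pid)
        return sorted(seen)


@dataclass
class GroundTruth:
    """Everything the simulator planted, for downstream verification."""

    cluster_labels: dict[str, str]
    abundance_series: pd.DataFrame  # phylotype x timepoint, columns sum to 1
    regime: RegimeParams | None = None
    env_table: pd.DataFrame | None = None
    read_sources: dict[str, dict[str, str]] = field(default_factory=dict)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    chars = list(seq)
    positions = rng.choice(len(chars), size=n_sub, replace=False)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(CODONS[aa][rng.integers(len(CODONS[aa]))] for aa in protein)


def generate_phylotype_pool(
    n_phylotypes: int,
    variants_per_phylotype: int = 1,
    seq_len_aa: int = 120,
    between_identity_max: float = 0.60,
    within_identity_min: float = 0.96,
    seed: int = 0,
    family: str = "gene",
    params: ClusteringParams = DEFAULT_PARAMS,
    max_attempts: int = 50,
) -> tuple[PhylotypePool, GroundTruth]:
    """Plant protein phylotypes with controlled identity structure.

    Each phylotype has one base protein (independent random sequences keep
    between-phylotype identity low) and ``variants_per_phylotype`` members
    derived by point substitutions, budgeted so any two members stay at or
    above ``within_identity_min`` global identity.  Every pairwise identity
    bound is verified post hoc with the clustering module's aligner;
    generation fails loudly rather than emit a pool violating its bounds.
    Coding sequences are consistent reverse translations (random synonymous
    codons).  Deterministic given ``seed``.
    """
    if n_phylotypes < 1 or variants_per_phylotype < 1:
        raise ParameterError("counts must be >= 1")
    if seq_len_aa < 50:
        raise ParameterError("seq_len_aa must be >= 50")
    if not (0 < between_identity_max < within_identity_min <= 1):
        raise ParameterError(
            "need 0 < between_identity_max < within_identity_min <= 1, got "
            f"{between_identity_max} / {within_identity_min}"
        )
    # substitutions per variant so that two variants (2k changed sites) stay
    # within the identity floor
    k = int(np.floor((1.0 - within_identity_min) * seq_len_aa / 2.0))
    if variants_per_phylotype > 1 and k == 0 and within_identity_min < 1.0:
        raise ParameterError(
            f"mutation budget unsatisfiable: seq_len_aa={seq_len_aa} too short "
            f"for within_identity_min={within_identity_min}"
        )
    rng = np.random.default_rng(seed)

    bases: list[str] = []
    for _ in range(n_phylotypes):
        for attempt in range(max_attempts):
            cand = _random_protein(rng, seq_len_aa)
            if all(
                global_align_identity(cand, b, params) <= between_identity_max
                for b in bases
            ):
                bases.append(cand)
                break
        else:
            raise ParameterError(
                f"could not draw a base protein with pairwise identity <= "
                f"{between_identity_max} after {max_attempts} attempts"
            )

    proteins: list[SeqRecord] = []
    cds: list[SeqRecord] = []
    labels: dict[str, str] = {}
    for p, base in enumerate(bases):
        pid = f"{family}_PT{p:03d}"
        for v in range(variants_per_phylotype):
            sid = f"{family}_p{p:03d}_v{v:02d}"
            prot = base if v == 0 else _mutate_protein(rng, base, k)
            proteins.append(make_record(prot, sid))
            cds.append(make_record(_reverse_translate(rng, prot), sid))
            labels[sid] = pid

    _verify_pool_identities(
        proteins, labels, within_identity_min, between_identity_max, params
    )
    pool = PhylotypePool(family, proteins, cds, labels)
    truth = GroundTruth(cluster_labels=dict(labels), abundance_series=pd.DataFrame())
    return pool, truth


def _verify_pool_identities(
    proteins: Sequence[SeqRecord],
    labels: Mapping[str, str],
    within_min: float,
    between_max: float,
    params: ClusteringParams,
) -> None:
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            a, b = proteins[i], proteins[j]
            ident = global_align_identity(a, b, params)
            same = labels[a.id] == labels[b.id]
            if same and ident < within_min:
                raise ParameterError(
                    f"planted within-phylotype identity {ident:.3f} < "
                    f"{within_min} for pair ({a.id}, {b.id})"
                )
            if not same and ident > between_max:
                raise ParameterError(
                    f"planted between-phylotype identity {ident:.3f} > "
                    f"{between_max} for pair ({a.id}, {b.id})"
                )


def simulate_abundance_series(
    params: RegimeParams, phylotype_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Relative-abundance trajectories (phylotype x timepoint).

    Initial abundances are a Dirichlet draw with concentration
    ``dominance_alpha``; log-abundances then follow independent Gaussian
    random walks with step ``walk_sigma`` and are mapped back through a
    softmax, so every column sums to 1.  ``walk_sigma = 0`` yields columns
    identical to the initial draw.
    """
    rng = np.random.default_rng(params.seed)
    n, t = params.n_phylotypes, params.n_timepoints
    if phylotype_ids is None:
        phylotype_ids = [f"PT{i:03d}" for i in range(n)]
    if len(phylotype_ids) != n:
        raise ParameterError("phylotype_ids length must equal n_phylotypes")
    initial = rng.dirichlet(np.full(n, params.dominance_alpha))
    # guard against exact zeros from extreme concentrations
    initial = np.clip(initial, 1e-12, None)
    x = np.log(initial)
    cols = []
    for _ in range(t):
        p = np.exp(x - x.max())
        cols.append(p / p.sum())
        x = x + rng.normal(0.0, params.walk_sigma, size=n)
    out = pd.DataFrame(
        np.column_stack(cols),
        index=list(phylotype_ids),
        columns=[f"T{k:02d}" for k in range(t)],
    )
    return out


def simulate_environment(
    n_timepoints: int = 11,
    shift_index: int = 6,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Environmental covariate table with a mid-series hydrologic shift.

    Emulates a riverbed mixing zone switching from surface-water intrusion
    (high dissolved organic carbon, low chloride) to groundwater discharge
    (the reverse): temperature follows a rise-then-fall seasonal arc,
    dissolved oxygen stays roughly constant, Cl⁻ steps up and NPOC steps
    down after ``shift_index`` samples.  Samples before the shift are
    labelled ``early``, the rest ``late``.
    """
    if not 0 < shift_index < n_timepoints:
        raise ParameterError(
            f"shift_index must be in (0, {n_timepoints}), got {shift_index}"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints)
    late = t >= shift_index
    temp = 8.0 + 12.0 * np.sin(np.pi * t / (n_timepoints - 1))
    do = np.full(n_timepoints, 9.0)
    cl = np.where(late, 12.0, 4.0).astype(float)
    npoc = np.where(late, 0.35, 0.9).astype(float)
    temp = temp + rng.normal(0, 0.6 * noise_scale, n_timepoints)
    do = do + rng.normal(0, 0.5 * noise_scale, n_timepoints)
    cl = cl + rng.normal(0, 0.8 * noise_scale, n_timepoints)
    npoc = np.clip(npoc + rng.normal(0, 0.05 * noise_scale, n_timepoints), 0.05, None)
    return pd.DataFrame(
        {
            "sample_id": [f"S{k:02d}" for k in t],
            "t_index": t,
            "date_label": [f"day_{21 * k:03d}" for k in t],
            "temp_c": temp,
            "do_mgL": do,
            "cl_mgL": cl,
            "npoc_mgL": npoc,
            "period": np.where(late, "late", "early"),
        }
    )


@dataclass
class FamilySim:
    """One gene family's inputs to read emission.

    ``carriage`` is the fraction of simulated individuals carrying the gene
    (the marker family has carriage 1 by definition).
    """

    name: str
    cds: list[SeqRecord]
    cluster_labels: Mapping[str, str]
    abundance: pd.DataFrame  # phylotype x timepoint
    carriage: float = 1.0

    def __post_init__(self):
        if not 0 < self.carriage <= 1:
            raise ParameterError(f"carriage must be in (0, 1], got {self.carriage}")


def _sequence_weights(families: Sequence[FamilySim], col: str) -> tuple[list, np.ndarray]:
    """Expected read weight per sequence: carriage x phylotype share x length."""
    seqs: list[tuple[str, SeqRecord]] = []
    weights: list[float] = []
    for fam in families:
        abund = fam.abundance[col]
        counts: dict[str, int] = {}
        for sid in (r.id for r in fam.cds):
            counts[fam.cluster_labels[sid]] = counts.get(fam.cluster_labels[sid], 0) + 1
        for rec in fam.cds:
            pid = fam.cluster_labels[rec.id]
            share = float(abund.loc[pid]) / counts[pid]
            seqs.append((fam.name, rec))
            weights.append(fam.carriage * share * len(rec.seq))
    return seqs, np.asarray(weights, dtype=float)


def emit_reads(
    families: Sequence[FamilySim] | FamilySim,
    marker: FamilySim | None,
    reads_per_sample: int = 100_000,
    read_len_nt: int = 100,
    error_rate: float = 0.005,
    seed: int = 0,
) -> tuple[dict[str, list[SeqRecord]], GroundTruth]:
    """Draw per-sample single-end reads from the planted community.

    Reads are sampled from coding sequences with probability proportional
    to carriage x phylotype relative abundance x gene length; the marker is
    one copy per individual, so its summed signal tracks total community
    size.  Substitution errors are applied per base at ``error_rate``.
    Returns reads keyed by sample id plus a GroundTruth carrying the
    read -> source-sequence map.  Deterministic given ``seed``.
    """
    if isinstance(families, FamilySim):
        families = [families]
    all_fams = list(families) + ([marker] if marker is not None else [])
    if marker is not None and marker.carriage != 1.0:
        raise ParameterError("marker family must have carriage 1.0")
    min_len = min(len(r.seq) for fam in all_fams for r in fam.cds)
    if read_len_nt > min_len:
        raise ParameterError(
            f"read_len_nt={read_len_nt} exceeds shortest coding sequence ({min_len})"
        )
    cols = list(all_fams[0].abundance.columns)
    for fam in all_fams:
        if list(fam.abundance.columns) != cols:
            raise ParameterError("all families must share the same timepoints")
        colsums = fam.abundance.sum(axis=0).to_numpy()
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ParameterError(f"abundance columns of {fam.name!r} must sum to 1")

    rng = np.random.default_rng(seed)
    nt = np.array(list("ACGT"))
    reads: dict[str, list[SeqRecord]] = {}
    sources: dict[str, dict[str, str]] = {}
    labels: dict[str, str] = {}
    for fam in all_fams:
        labels.update(fam.cluster_labels)

    for s_idx, col in enumerate(cols):
        sample_id = f"S{s_idx:02d}"
        sample_reads: list[SeqRecord] = []
        src: dict[str, str] = {}
        if reads_per_sample == 0:
            warnings.warn(f"sample {sample_id}: reads_per_sample=0, emitting no reads")
            reads[sample_id] = sample_reads
            sources[sample_id] = src
            continue
        seqs, weights = _sequence_weights(all_fams, col)
        probs = weights / weights.sum()
        counts = rng.multinomial(reads_per_sample, probs)
        r_idx = 0
        for (fam_name, rec), c in zip(seqs, counts):
            if c == 0:
                continue
            seq_str = str(rec.seq)
            offsets = rng.integers(0, len(seq_str) - read_len_nt + 1, size=c)
            for off in offsets:
                frag = seq_str[off : off + read_len_nt]
                n_err = rng.binomial(read_len_nt, error_rate)
                if n_err:
                    chars = list(frag)
                    for pos in rng.choice(read_len_nt, size=n_err, replace=False):
                        alt = [b for b in "ACGT" if b != chars[pos]]
                        chars[pos] = alt[rng.integers(3)]
                    frag = "".join(chars)
                rid = f"{sample_id}_r{r_idx:07d}"
                r_idx += 1
                sample_reads.append(make_record(frag, rid))
                src[rid] = rec.id
        reads[sample_id] = sample_reads
        sources[sample_id] = src

    abund = pd.concat(
        [fam.abundance for fam in all_fams], keys=[f.name for f in all_fams]
    )
    truth = GroundTruth(
        cluster_labels=labels, abundance_series=abund, read_sources=sources
    )
    return reads, truth
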
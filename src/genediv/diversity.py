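"""Within-gene diversity surfaces: richness, inverse Simpson, cumulative
profiles, turnover (mean abundance variance) and Bray–Curtis distance-decay.

Richness is the number of phylotypes with nonzero relative abundance;
diversity is the inverse Simpson index 1/Σpᵢ², which equals richness under
perfect evenness and 1 for a single phylotype.  Cumulative profiles pool
RPKM from each timepoint with all previous ones before renormalising, so
cumulative richness is exactly the union of phylotypes observed so far.
Turnover of one gene family is the mean over phylotypes of the temporal
variance of relative abundance (unbiased, unobserved timepoints counted as
zero abundance): resistant families score low, families whose phylotypes
are recruited and lost score high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis

from .errors import DegenerateInputError, InputError
from .stats import linear_regression


@dataclass
class TurnoverSummary:
    """One gene family's richness and turnover (one summary-table row)."""

    gene_family: str
    phylotype_richness: int
    mean_abundance_variance: float

    def __post_init__(self):
        if self.phylotype_richness < 0 or self.mean_abundance_variance < 0:
            raise InputError("richness and variance must be non-negative")


def richness(profile) -> int:
    """Number of entries with abundance > 0."""
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise InputError("abundances must be non-negative")
    return int((p > 0).sum())


def inverse_simpson(profile, renorm_tol: float = 1e-6) -> float:
    """Inverse Simpson diversity 1/Σpᵢ² of a relative-abundance profile.

    The profile must sum to 1 within ``renorm_tol`` (it is renormalised
    internally); an all-zero profile is defined as 0 by convention so that
    time series with unobserved samples stay rectangular.
    """
    p = np.asarray(profile, dtype=float)
    if (p < 0).any():
        raise InputError("abundances must be non-negative")
    total = p.sum()
    if total == 0:
        return 0.0
    if abs(total - 1.0) > renorm_tol:
        raise InputError(f"profile sums to {total:.6g}, not 1 (tol {renorm_tol})")
    p = p / total
    return 1.0 / float((p**2).sum())


def cumulative_profiles(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample and cumulative diversity from a time-ordered RPKM matrix.

    Columns of ``matrix`` (phylotype x sample, RPKM or raw abundance) must
    already be in time order.  The cumulative profile at timepoint t pools
    (sums) columns 1..t and renormalises; richness and inverse Simpson are
    computed on each per-sample and cumulative profile, and delta series
    subtract the first timepoint's value.
    """
    if matrix.shape[1] < 1:
        raise InputError("need at least one sample column")
    rows = []
    cum = np.zeros(matrix.shape[0])
    for col in matrix.columns:
        v = matrix[col].to_numpy(dtype=float)
        cum = cum + v
        vs, cs = v.sum(), cum.sum()
        rows.append(
            {
                "sample_id": col,
                "richness": richness(v),
                "inv_simpson": inverse_simpson(v / vs) if vs > 0 else 0.0,
                "cum_richness": richness(cum),
                "cum_inv_simpson": inverse_simpson(cum / cs) if cs > 0 else 0.0,
            }
        )
    out = pd.DataFrame(rows)
    out["delta_richness"] = out["cum_richness"] - out["cum_richness"].iloc[0]
    out["delta_inv_simpson"] = out["cum_inv_simpson"] - out["cum_inv_simpson"].iloc[0]
    return out


def mean_abundance_variance(rel_matrix: pd.DataFrame, ddof: int = 1) -> float:
    """Turnover: mean over phylotypes of the temporal variance of relative
    abundance.

    Unobserved timepoints enter as zero abundance.  The variance is the
    unbiased (n−1) estimator by default; set ``ddof=0`` for the population
    version (the absolute value of published turnover numbers depends on
    this choice).  Note that appending an all-zero phylotype row lowers the
    mean — rows should be the phylotypes observed for the family.
    """
    if rel_matrix.shape[1] < 2:
        raise InputError("need >= 2 timepoints for a temporal variance")
    values = rel_matrix.to_numpy(dtype=float)
    return float(values.var(axis=1, ddof=ddof).mean())


def turnover_summary(
    gene_family: str, rel_matrix: pd.DataFrame, ddof: int = 1
) -> TurnoverSummary:
    """Summary-table row: total observed richness + mean abundance variance."""
    observed = (rel_matrix.to_numpy(dtype=float) > 0).any(axis=1)
    return TurnoverSummary(
        gene_family=gene_family,
        phylotype_richness=int(observed.sum()),
        mean_abundance_variance=mean_abundance_variance(rel_matrix, ddof=ddof),
    )


def bray_curtis(u, v) -> float:
    """Bray–Curtis dissimilarity Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ), in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InputError("profiles must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise InputError("abundances must be non-negative")
    if u.sum() == 0 and v.sum() == 0:
        raise DegenerateInputError("Bray–Curtis undefined for two all-zero profiles")
    return float(_braycurtis(u, v))


def distance_decay(
    matrix: pd.DataFrame, times: pd.Series | np.ndarray | None = None
) -> tuple[pd.DataFrame, float]:
    """All-pairs Bray–Curtis dissimilarity against time lag.

    ``times`` gives each sample column's position in time (defaults to
    column index, i.e. lag in sample units; pass calendar days for a
    calendar-distance axis).  Returns the n(n−1)/2 pair table and the
    least-squares slope of dissimilarity on lag.
    """
    n = matrix.shape[1]
    if n < 2:
        raise InputError("need >= 2 samples")
    t = np.arange(n, dtype=float) if times is None else np.asarray(times, dtype=float)
    if t.shape[0] != n:
        raise InputError("times must match the number of sample columns")
    cols = list(matrix.columns)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rows.append(
                {
                    "sample_i": cols[i],
                    "sample_j": cols[j],
                    "lag": abs(t[j] - t[i]),
                    "dissimilarity": bray_curtis(matrix[cols[i]], matrix[cols[j]]),
                }
            )
    pairs = pd.DataFrame(rows)
    if pairs["lag"].nunique() > 1:
        slope = linear_regression(pairs["lag"], pairs["dissimilarity"]).slope
    else:
        slope = float("nan")
    return pairs, slope
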
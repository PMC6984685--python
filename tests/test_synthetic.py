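"""Synthetic community generator: planted identity structure, abundance
dynamics, environment series and read emission."""

import numpy as np
import pytest

from genediv import (
    FamilySim,
    RegimeParams,
    emit_reads,
    generate_phylotype_pool,
    global_align_identity,
    simulate_abundance_series,
    simulate_environment,
)
from genediv.errors import ParameterError
from genediv.io import write_fasta


def test_degenerate_pool_single_sequence():
    pool, truth = generate_phylotype_pool(1, 1, 60, seed=0)
    assert len(pool.proteins) == 1
    assert truth.cluster_labels == {pool.proteins[0].id: "gene_PT000"}


def test_pool_identity_bounds_hold(small_pool):
    pool, truth = small_pool
    labels = truth.cluster_labels
    prots = pool.proteins
    for i in range(len(prots)):
        for j in range(i + 1, len(prots)):
            ident = global_align_identity(prots[i], prots[j])
            if labels[prots[i].id] == labels[prots[j].id]:
                assert ident >= 0.96
            else:
                assert ident <= 0.60


def test_pool_two_phylotypes_three_variants_margins():
    pool, truth = generate_phylotype_pool(
        2, 3, 80, between_identity_max=0.60, within_identity_min=0.95, seed=2
    )
    labels = truth.cluster_labels
    within = between = 0
    for i in range(len(pool.proteins)):
        for j in range(i + 1, len(pool.proteins)):
            a, b = pool.proteins[i], pool.proteins[j]
            ident = global_align_identity(a, b)
            if labels[a.id] == labels[b.id]:
                within += 1
                assert ident >= 0.95
            else:
                between += 1
                assert ident <= 0.60
    assert within == 6 and between == 9


def test_pool_deterministic_fasta_bytes(tmp_path):
    for name in ("a", "b"):
        pool, _ = generate_phylotype_pool(3, 2, 60, seed=9)
        write_fasta(pool.proteins, tmp_path / f"{name}.fasta")
        write_fasta(pool.cds, tmp_path / f"{name}_cds.fasta")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
    assert (
        tmp_path / "a_cds.fasta"
    ).read_bytes() == (tmp_path / "b_cds.fasta").read_bytes()


def test_cds_translates_back_to_protein(small_pool):
    from Bio.Seq import Seq

    pool, _ = small_pool
    prot = {r.id: str(r.seq) for r in pool.proteins}
    for rec in pool.cds:
        assert str(Seq(str(rec.seq)).translate()) == prot[rec.id]


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(between_identity_max=0.97, within_identity_min=0.96),  # crossed bounds
        dict(seq_len_aa=40),  # below minimum length
        dict(within_identity_min=0.999, variants_per_phylotype=2, seq_len_aa=60),
    ],
)
def test_pool_infeasible_parameters_raise(kwargs):
    base = dict(n_phylotypes=2, variants_per_phylotype=2, seq_len_aa=80, seed=0)
    base.update(kwargs)
    with pytest.raises(ParameterError):
        generate_phylotype_pool(**base)


def test_abundance_zero_sigma_is_constant():
    params = RegimeParams("resistant", 6, 8, walk_sigma=0.0, seed=1)
    ab = simulate_abundance_series(params)
    assert np.allclose(ab.to_numpy(), ab.to_numpy()[:, [0]])
    assert np.allclose(ab.sum(axis=0), 1.0, atol=1e-9)


def test_abundance_single_phylotype_all_one():
    ab = simulate_abundance_series(RegimeParams("resistant", 1, 5, seed=2))
    assert np.allclose(ab.to_numpy(), 1.0)


def test_abundance_columns_sum_to_one_across_regimes():
    for seed in range(5):
        for sigma in (0.0, 0.1, 1.5):
            ab = simulate_abundance_series(
                RegimeParams("r", 12, 7, walk_sigma=sigma, seed=seed)
            )
            assert np.allclose(ab.sum(axis=0), 1.0, atol=1e-9)
            assert (ab.to_numpy() >= 0).all()


def test_regime_params_validation():
    with pytest.raises(ParameterError):
        RegimeParams("r", 0, 5)
    with pytest.raises(ParameterError):
        RegimeParams("r", 3, 1)
    with pytest.raises(ParameterError):
        RegimeParams("r", 3, 5, walk_sigma=-0.1)


def test_environment_period_split_and_shift():
    env = simulate_environment(11, 6, seed=3)
    assert (env["period"] == "early").sum() == 6
    assert (env["period"] == "late").sum() == 5
    quiet = simulate_environment(11, 6, seed=3, noise_scale=0.0)
    early = quiet["period"] == "early"
    assert quiet.loc[~early, "cl_mgL"].mean() > quiet.loc[early, "cl_mgL"].mean()
    assert quiet.loc[~early, "npoc_mgL"].mean() < quiet.loc[early, "npoc_mgL"].mean()


def test_environment_deterministic_and_validated():
    a = simulate_environment(11, 6, seed=4)
    b = simulate_environment(11, 6, seed=4)
    assert a.equals(b)
    with pytest.raises(ParameterError):
        simulate_environment(11, 11, seed=0)
    with pytest.raises(ParameterError):
        simulate_environment(11, 0, seed=0)


def _single_family(n_pt, sigma, seed, carriage=1.0, n_t=3):
    pool, _ = generate_phylotype_pool(n_pt, 1, 60, seed=seed, family=f"f{seed}")
    ab = simulate_abundance_series(
        RegimeParams("r", n_pt, n_t, walk_sigma=sigma, seed=seed), pool.phylotype_ids
    )
    return pool, FamilySim(f"f{seed}", pool.cds, pool.cluster_labels, ab, carriage)


def test_reads_from_single_phylotype_all_trace_back():
    pool, fam = _single_family(1, 0.0, seed=21)
    mpool, marker = _single_family(1, 0.0, seed=22)
    reads, truth = emit_reads(fam, marker.__class__(
        "rplB_like", mpool.cds, mpool.cluster_labels, marker.abundance, 1.0
    ), reads_per_sample=100, read_len_nt=60, error_rate=0.0, seed=5)
    gene_id = pool.cds[0].id
    gene_seq = str(pool.cds[0].seq)
    for sample, src in truth.read_sources.items():
        for rid, source in src.items():
            rec = next(r for r in reads[sample] if r.id == rid)
            if source == gene_id:
                # error-free reads are exact substrings of the source gene
                assert str(rec.seq) in gene_seq


def test_read_allocation_follows_abundance_binomially():
    # phylotype A at 0.8 vs B at 0.2, equal lengths: A gets 4x B's reads
    import pandas as pd

    pool, _ = generate_phylotype_pool(2, 1, 60, seed=31, family="ab")
    ab = pd.DataFrame({"T00": [0.8, 0.2]}, index=pool.phylotype_ids)
    fam = FamilySim("ab", pool.cds, pool.cluster_labels, ab, 1.0)
    reads, truth = emit_reads(
        [fam], None, reads_per_sample=10_000, read_len_nt=60, error_rate=0.0, seed=6
    )
    src = truth.read_sources["S00"]
    label = truth.cluster_labels
    n_a = sum(1 for s in src.values() if label[s] == pool.phylotype_ids[0])
    # 99% binomial interval around p = 0.8 with n = 10,000
    se = np.sqrt(0.8 * 0.2 / 10_000)
    assert abs(n_a / 10_000 - 0.8) < 2.576 * se


def test_emit_reads_zero_reads_warns_not_raises():
    _, fam = _single_family(2, 0.1, seed=41)
    with pytest.warns(UserWarning, match="reads_per_sample=0"):
        reads, _ = emit_reads(fam, None, reads_per_sample=0, read_len_nt=60, seed=7)
    assert all(len(v) == 0 for v in reads.values())


def test_emit_reads_validates_read_length_and_carriage():
    _, fam = _single_family(2, 0.1, seed=51)
    with pytest.raises(ParameterError, match="read_len_nt"):
        emit_reads(fam, None, reads_per_sample=10, read_len_nt=10_000, seed=8)
    with pytest.raises(ParameterError, match="carriage"):
        FamilySim("x", fam.cds, fam.cluster_labels, fam.abundance, carriage=1.5)


def test_emit_reads_deterministic():
    _, fam = _single_family(3, 0.2, seed=61)
    out = []
    for _ in range(2):
        reads, _ = emit_reads(fam, None, reads_per_sample=200, read_len_nt=60, seed=9)
        out.append([(r.id, str(r.seq)) for recs in reads.values() for r in recs])
    assert out[0] == out[1]
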
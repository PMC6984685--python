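"""End-to-end orchestration: simulate → cluster → profile → diversity → stats.

A :class:`RunConfig` describes either a simulated community (per-family
regime parameters) or real inputs (reference FASTAs plus per-sample read
files); :func:`run_all` executes the stages in dependency order into an
output tree and writes a JSON manifest with the config snapshot, per-stage
wall time and a checksum of every output file, so a rerun with the same
config and seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import io as gio
from . import stats as st
from .clustering import (
    ClusteringParams,
    build_guide_tree,
    greedy_cluster,
    guide_tree_leaf_order,
    membership_map,
)
from .errors import DegenerateInputError, InputError, ParameterError
from .profiling import (
    ReadRecruiter,
    RecruitmentParams,
    per_capita_abundance,
    phylotype_relative_abundance,
    rpkm_matrix,
    sum_by_phylotype,
)
from .synthetic import (
    FamilySim,
    RegimeParams,
    emit_reads,
    generate_phylotype_pool,
    simulate_abundance_series,
    simulate_environment,
)

log = logging.getLogger("genediv")

MARKER_FAMILY = "rplB_like"


@dataclass
class FamilyConfig:
    """One gene family: either simulation parameters or real reference files."""

    name: str
    n_phylotypes: int | None = None
    variants_per_phylotype: int = 1
    walk_sigma: float | None = None
    dominance_alpha: float = 1.0
    carriage: float = 1.0
    regime: str = "resistant"
    proteins_fasta: str | None = None
    cds_fasta: str | None = None

    def __post_init__(self):
        simulated = self.n_phylotypes is not None or self.walk_sigma is not None
        real = self.proteins_fasta is not None or self.cds_fasta is not None
        if simulated and real:
            raise ParameterError(
                f"family {self.name!r}: supply either simulation parameters or "
                "reference FASTA paths, not both"
            )
        if not simulated and not real:
            raise ParameterError(f"family {self.name!r}: no inputs supplied")
        if real and (self.proteins_fasta is None or self.cds_fasta is None):
            raise ParameterError(
                f"family {self.name!r}: real input needs both protein and CDS FASTA"
            )

    @property
    def is_simulated(self) -> bool:
        return self.proteins_fasta is None


@dataclass
class RunConfig:
    families: list[FamilyConfig] = field(default_factory=list)
    marker_n_phylotypes: int = 40
    marker_walk_sigma: float = 0.05
    n_timepoints: int = 11
    shift_index: int = 6
    reads_per_sample: int = 20_000
    read_len_nt: int = 100
    error_rate: float = 0.005
    seq_len_aa: int = 120
    between_identity_max: float = 0.60
    within_identity_min: float = 0.96
    clustering_threshold: float = 0.90
    min_nucleotide_identity: float = 0.95
    variance_ddof: int = 1
    seed: int = 0
    reads_dir: str | None = None
    metadata_path: str | None = None

    def __post_init__(self):
        if not self.families:
            raise ParameterError("config needs at least one gene family")
        any_real = any(not f.is_simulated for f in self.families)
        if any_real and (self.reads_dir is None or self.metadata_path is None):
            raise ParameterError(
                "real reference inputs require reads_dir and metadata_path"
            )

    @property
    def clustering_params(self) -> ClusteringParams:
        return ClusteringParams(threshold=self.clustering_threshold)

    @property
    def recruitment_params(self) -> RecruitmentParams:
        return RecruitmentParams(min_nucleotide_identity=self.min_nucleotide_identity)


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Load a YAML run configuration; ``seed`` overrides the file's value."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    families = [FamilyConfig(**f) for f in raw.pop("families", [])]
    cfg = RunConfig(families=families, **raw)
    if seed is not None:
        cfg.seed = seed
    return cfg


def demo_config(seed: int = 0, reads_per_sample: int = 20_000) -> RunConfig:
    """Six N-cycling-style gene families spanning the observed regimes.

    Richness and dynamics span the qualitative spectrum seen for
    N-cycling genes:
    high-richness/stable (narG- and nosZ-like, resistant), lower-richness/
    high-turnover (nirKS- and norB-like, resilient), and two low-richness
    nitrification-style families (2-phylotype amoA-like; 7-phylotype
    nxrA-like with one dominant member).  Carriage fractions follow the
    per-capita abundance ranges reported for each gene class.
    """
    fams = [
        FamilyConfig("narG_like", n_phylotypes=52, walk_sigma=0.05, carriage=0.28),
        FamilyConfig("nosZ_like", n_phylotypes=51, walk_sigma=0.15, carriage=0.25),
        FamilyConfig(
            "norB_like", n_phylotypes=31, walk_sigma=0.5, carriage=0.16,
            regime="resilient",
        ),
        FamilyConfig(
            "nirKS_like", n_phylotypes=23, walk_sigma=0.5, carriage=0.40,
            regime="resilient",
        ),
        FamilyConfig(
            "nxrA_like", n_phylotypes=7, walk_sigma=0.05, dominance_alpha=0.15,
            carriage=0.10, regime="low_richness",
        ),
        FamilyConfig(
            "amoA_like", n_phylotypes=2, walk_sigma=0.3, dominance_alpha=0.5,
            carriage=0.15, regime="low_richness",
        ),
    ]
    return RunConfig(families=fams, seed=seed, reads_per_sample=reads_per_sample)


def _child_seed(seed: int, tag: str) -> int:
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    """Generate pools, abundance series, environment and reads; write files."""
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "reads").mkdir(exist_ok=True)
    env = simulate_environment(
        cfg.n_timepoints, cfg.shift_index, seed=_child_seed(cfg.seed, "env")
    )
    gio.write_table(env, outdir / "metadata.tsv")

    sims: list[FamilySim] = []
    for fam in cfg.families:
        pool, _ = generate_phylotype_pool(
            fam.n_phylotypes,
            fam.variants_per_phylotype,
            cfg.seq_len_aa,
            cfg.between_identity_max,
            cfg.within_identity_min,
            seed=_child_seed(cfg.seed, f"pool:{fam.name}"),
            family=fam.name,
            params=cfg.clustering_params,
        )
        regime = RegimeParams(
            name=fam.regime,
            n_phylotypes=fam.n_phylotypes,
            n_timepoints=cfg.n_timepoints,
            walk_sigma=fam.walk_sigma,
            dominance_alpha=fam.dominance_alpha,
            seed=_child_seed(cfg.seed, f"abund:{fam.name}"),
        )
        abund = simulate_abundance_series(regime, pool.phylotype_ids)
        sims.append(
            FamilySim(fam.name, pool.cds, pool.cluster_labels, abund, fam.carriage)
        )
        gio.write_fasta(pool.proteins, outdir / f"{fam.name}_proteins.fasta")
        gio.write_fasta(pool.cds, outdir / f"{fam.name}_cds.fasta")
        gio.write_table(
            pd.DataFrame(
                sorted(pool.cluster_labels.items()),
                columns=["sequence_id", "phylotype_id"],
            ),
            outdir / f"{fam.name}_truth_labels.tsv",
        )
        gio.write_table(
            abund.rename_axis("phylotype_id").reset_index(),
            outdir / f"{fam.name}_truth_abundance.tsv",
        )

    marker_pool, _ = generate_phylotype_pool(
        cfg.marker_n_phylotypes,
        1,
        cfg.seq_len_aa,
        cfg.between_identity_max,
        cfg.within_identity_min,
        seed=_child_seed(cfg.seed, "pool:marker"),
        family=MARKER_FAMILY,
        params=cfg.clustering_params,
    )
    marker_regime = RegimeParams(
        name="marker",
        n_phylotypes=cfg.marker_n_phylotypes,
        n_timepoints=cfg.n_timepoints,
        walk_sigma=cfg.marker_walk_sigma,
        seed=_child_seed(cfg.seed, "abund:marker"),
    )
    marker_abund = simulate_abundance_series(marker_regime, marker_pool.phylotype_ids)
    marker = FamilySim(
        MARKER_FAMILY, marker_pool.cds, marker_pool.cluster_labels, marker_abund, 1.0
    )
    gio.write_fasta(marker_pool.proteins, outdir / f"{MARKER_FAMILY}_proteins.fasta")
    gio.write_fasta(marker_pool.cds, outdir / f"{MARKER_FAMILY}_cds.fasta")
    gio.write_table(
        pd.DataFrame(
            sorted(marker_pool.cluster_labels.items()),
            columns=["sequence_id", "phylotype_id"],
        ),
        outdir / f"{MARKER_FAMILY}_truth_labels.tsv",
    )

    reads, truth = emit_reads(
        sims,
        marker,
        reads_per_sample=cfg.reads_per_sample,
        read_len_nt=cfg.read_len_nt,
        error_rate=cfg.error_rate,
        seed=_child_seed(cfg.seed, "reads"),
    )
    env = env.set_index("sample_id")
    totals = {}
    for sample_id, recs in reads.items():
        gio.write_fastq(recs, outdir / "reads" / f"{sample_id}.fastq")
        totals[sample_id] = len(recs)
    env["total_reads"] = pd.Series(totals).reindex(env.index).fillna(0).astype(int)
    gio.write_table(env.reset_index(), outdir / "metadata.tsv")
    return {"families": sims, "marker": marker, "env": env, "truth": truth}


def stage_cluster(cfg: RunConfig, proteins_by_family: dict, outdir: Path) -> dict:
    """Cluster each family's proteins into phylotypes; write membership,
    representatives and a UPGMA guide tree per family."""
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for fam, proteins in proteins_by_family.items():
        phylotypes = greedy_cluster(proteins, cfg.clustering_params, family=fam)
        members = membership_map(phylotypes)
        rep_ids = {pt.representative for pt in phylotypes}
        rows = [
            {
                "sequence_id": sid,
                "phylotype_id": pid,
                "representative_flag": int(sid in rep_ids),
            }
            for sid, pid in sorted(members.items())
        ]
        gio.write_table(pd.DataFrame(rows), outdir / f"{fam}_membership.tsv")
        rep_records = [r for r in proteins if r.id in rep_ids]
        gio.write_fasta(rep_records, outdir / f"{fam}_representatives.fasta")
        newick = build_guide_tree(rep_records, cfg.clustering_params)
        (outdir / f"{fam}.nwk").write_text(newick + "\n")
        rep_to_pt = {pt.representative: pt.phylotype_id for pt in phylotypes}
        leaf_order = [rep_to_pt[r] for r in guide_tree_leaf_order(newick)]
        out[fam] = {
            "phylotypes": phylotypes,
            "membership": members,
            "leaf_order": leaf_order,
        }
    return out


def stage_profile(
    cfg: RunConfig,
    reads_by_sample: dict,
    cds_by_family: dict,
    membership_by_family: dict,
    env: pd.DataFrame,
    outdir: Path,
    leaf_order_by_family: dict | None = None,
) -> dict:
    """Recruit reads, convert to RPKM, phylotype relative abundance and
    per-capita gene abundance."""
    outdir.mkdir(parents=True, exist_ok=True)
    all_refs = [r for recs in cds_by_family.values() for r in recs]
    recruiter = ReadRecruiter(all_refs, cfg.recruitment_params)
    samples = list(env.index)
    counts = {}
    unassigned = {}
    for s in samples:
        counts[s], unassigned[s] = recruiter.recruit(reads_by_sample.get(s, []))
        log.info("profile: %s — %d reads unassigned", s, unassigned[s])
    count_df = pd.DataFrame(counts)[samples]
    gio.write_table(
        count_df.rename_axis("sequence_id").reset_index(), outdir / "counts.tsv"
    )
    totals = env["total_reads"]
    rpkms = rpkm_matrix(count_df, recruiter.ref_lengths, totals)
    gio.write_table(
        rpkms.rename_axis("sequence_id").reset_index(), outdir / "rpkm.tsv"
    )

    seq_to_family = {
        r.id: fam for fam, recs in cds_by_family.items() for r in recs
    }
    marker_rpkm = rpkms.loc[[i for i in rpkms.index if seq_to_family[i] == MARKER_FAMILY]]
    rel = {}
    pt_rpkm = {}
    per_capita_rows = {}
    for fam, membership in membership_by_family.items():
        if fam == MARKER_FAMILY:
            continue
        fam_rpkm = rpkms.loc[[i for i in rpkms.index if seq_to_family[i] == fam]]
        pt_rpkm[fam] = sum_by_phylotype(fam_rpkm, membership)
        rel[fam] = phylotype_relative_abundance(pt_rpkm[fam])
        if leaf_order_by_family and fam in leaf_order_by_family:
            # heatmap convention: rows follow the guide tree's leaf order
            order = [p for p in leaf_order_by_family[fam] if p in rel[fam].index]
            rel[fam] = rel[fam].reindex(order)
        gio.write_table(
            rel[fam].rename_axis("phylotype_id").reset_index(),
            outdir / f"{fam}_relative_abundance.tsv",
        )
        per_capita_rows[fam] = per_capita_abundance(fam_rpkm, marker_rpkm)
    per_capita = pd.DataFrame(per_capita_rows).T[samples]
    gio.write_table(
        per_capita.rename_axis("gene_family").reset_index(), outdir / "per_capita.tsv"
    )
    return {
        "counts": count_df,
        "rpkm": rpkms,
        "phylotype_rpkm": pt_rpkm,
        "relative_abundance": rel,
        "per_capita": per_capita,
        "marker_rpkm": marker_rpkm,
    }


def stage_diversity(cfg: RunConfig, profile: dict, env: pd.DataFrame, outdir: Path) -> dict:
    """Diversity profiles, turnover summaries and distance-decay tables."""
    outdir.mkdir(parents=True, exist_ok=True)
    diversity_tables = {}
    turnover_rows = []
    slopes = []
    for fam, rel_matrix in profile["relative_abundance"].items():
        prof = dv.cumulative_profiles(profile["phylotype_rpkm"][fam])
        gio.write_table(prof, outdir / f"{fam}_diversity.tsv")
        diversity_tables[fam] = prof
        summary = dv.turnover_summary(fam, rel_matrix, ddof=cfg.variance_ddof)
        turnover_rows.append(
            {
                "gene_family": fam,
                "phylotype_richness": summary.phylotype_richness,
                "mean_abundance_variance": summary.mean_abundance_variance,
            }
        )
        pairs, slope = dv.distance_decay(rel_matrix, env["t_index"])
        gio.write_table(pairs, outdir / f"{fam}_distance_decay.tsv")
        slopes.append({"gene_family": fam, "slope": slope})
    turnover = pd.DataFrame(turnover_rows)
    gio.write_table(turnover, outdir / "turnover.tsv")
    gio.write_table(pd.DataFrame(slopes), outdir / "distance_decay_slopes.tsv")
    return {"diversity": diversity_tables, "turnover": turnover}


def stage_stats(
    cfg: RunConfig, profile: dict, diversity_tables: dict, env: pd.DataFrame, outdir: Path
) -> dict:
    """Inferential comparisons: richness Welch tests, profile-variability
    Levene tests, early-vs-late Mann–Whitney on per-capita abundance, the
    covariate correlation matrix and the regression grid."""
    outdir.mkdir(parents=True, exist_ok=True)
    fams = sorted(profile["relative_abundance"])

    welch_rows = []
    for i, a in enumerate(fams):
        for b in fams[i + 1 :]:
            try:
                res = st.welch_t_test(
                    diversity_tables[a]["richness"], diversity_tables[b]["richness"]
                )
                row = {"family_a": a, "family_b": b, "t": res.statistic,
                       "df": res.df, "p": res.pvalue}
            except DegenerateInputError:
                # both richness series constant: nothing to test
                row = {"family_a": a, "family_b": b, "t": float("nan"),
                       "df": float("nan"), "p": float("nan")}
            welch_rows.append(row)
    gio.write_table(pd.DataFrame(welch_rows), outdir / "richness_welch.tsv")

    levene = st.profile_variability_levene(profile["relative_abundance"])
    gio.write_table(levene, outdir / "variability_levene.tsv")

    early = env.index[env["period"] == "early"]
    late = env.index[env["period"] == "late"]
    mw_rows = []
    for fam in fams:
        pc = profile["per_capita"].loc[fam]
        try:
            res = st.mann_whitney(pc[early], pc[late])
            mw_rows.append(
                {"gene_family": fam, "U": res.statistic, "p": res.pvalue,
                 "method": res.name}
            )
        except DegenerateInputError:
            mw_rows.append(
                {"gene_family": fam, "U": float("nan"), "p": float("nan"),
                 "method": "undefined"}
            )
    gio.write_table(pd.DataFrame(mw_rows), outdir / "per_capita_mannwhitney.tsv")

    covariates = env[["temp_c", "do_mgL", "cl_mgL", "npoc_mgL"]]
    corr = st.pearson_correlation_matrix(covariates)
    gio.write_table(corr.rename_axis("covariate").reset_index(),
                    outdir / "env_correlation.tsv")

    metrics = {}
    for fam in fams:
        prof = diversity_tables[fam].set_index("sample_id")
        metrics[f"{fam}:diversity"] = prof["inv_simpson"]
        metrics[f"{fam}:richness"] = prof["richness"].astype(float)
        metrics[f"{fam}:abundance"] = profile["per_capita"].loc[fam]
    metrics_df = pd.DataFrame(metrics).reindex(env.index)
    grid = st.env_regression_grid(metrics_df, covariates)
    gio.write_table(grid, outdir / "regression_grid.tsv")
    return {"welch": welch_rows, "levene": levene, "mannwhitney": mw_rows,
            "grid": grid}


def _load_real_inputs(cfg: RunConfig) -> dict:
    env = gio.read_table(
        cfg.metadata_path,
        required=["sample_id", "t_index", "period", "total_reads"],
        index_col=None,
    ).set_index("sample_id")
    reads = {}
    for s in env.index:
        path = Path(cfg.reads_dir) / f"{s}.fastq"
        if not path.exists():
            raise InputError(f"missing read file for sample {s!r}: {path}")
        reads[s] = gio.read_fastq(path)
    proteins = {}
    cds = {}
    for fam in cfg.families:
        proteins[fam.name] = gio.read_fasta(fam.proteins_fasta)
        cds[fam.name] = gio.read_fasta(fam.cds_fasta)
    return {"env": env, "reads": reads, "proteins": proteins, "cds": cds}


def run_all(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage in dependency order; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_snapshot(cfg),
        "seed": cfg.seed,
        "stages": {},
    }
    timings = {}

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        result = fn(*args)
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.1fs", name, timings[name])
        return result

    all_simulated = all(f.is_simulated for f in cfg.families)
    if all_simulated:
        sim = timed("simulate", stage_simulate, cfg, outdir / "simulate")
        env = sim["env"]
        reads = {
            s: gio.read_fastq(outdir / "simulate" / "reads" / f"{s}.fastq")
            for s in env.index
        }
        proteins_by_family = {
            f.name: gio.read_fasta(outdir / "simulate" / f"{f.name}_proteins.fasta")
            for f in cfg.families
        }
        proteins_by_family[MARKER_FAMILY] = gio.read_fasta(
            outdir / "simulate" / f"{MARKER_FAMILY}_proteins.fasta"
        )
        cds_by_family = {
            f.name: gio.read_fasta(outdir / "simulate" / f"{f.name}_cds.fasta")
            for f in cfg.families
        }
        cds_by_family[MARKER_FAMILY] = gio.read_fasta(
            outdir / "simulate" / f"{MARKER_FAMILY}_cds.fasta"
        )
    else:
        real = _load_real_inputs(cfg)
        env, reads = real["env"], real["reads"]
        proteins_by_family, cds_by_family = real["proteins"], real["cds"]
        if MARKER_FAMILY not in proteins_by_family:
            raise InputError(
                f"real-input runs must include a {MARKER_FAMILY!r} marker family"
            )

    clusters = timed("cluster", stage_cluster, cfg, proteins_by_family,
                     outdir / "cluster")
    membership_by_family = {f: c["membership"] for f, c in clusters.items()}
    leaf_orders = {f: c["leaf_order"] for f, c in clusters.items()}
    profile = timed(
        "profile", stage_profile, cfg, reads, cds_by_family,
        membership_by_family, env, outdir / "profile", leaf_orders,
    )
    divstage = timed("diversity", stage_diversity, cfg, profile, env,
                     outdir / "diversity")
    timed("stats", stage_stats, cfg, profile, divstage["diversity"], env,
          outdir / "stats")

    checksums = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            checksums[str(path.relative_to(outdir))] = _sha256(path)
    manifest["stages"] = timings
    manifest["checksums"] = checksums
    gio.write_json(manifest, outdir / "manifest.json")
    return manifest


def _config_snapshot(cfg: RunConfig) -> dict:
    snap = asdict(cfg)
    snap["clustering"] = asdict(cfg.clustering_params)
    snap["recruitment"] = asdict(cfg.recruitment_params)
    return json.loads(json.dumps(snap))
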
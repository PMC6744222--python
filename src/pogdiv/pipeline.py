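"""End-to-end orchestration of the per-pair and cross-pair analyses."""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import CodonAlignment, align_codons
from .associations import (
    TaxonPairRecord,
    gene_level_time_correlation,
    pair_level_associations,
)
from .cluster import ClusterTestResult, cluster_test, substitution_positions
from .config import RunConfig
from .io import (
    read_fasta,
    write_cluster_tsv,
    write_estimates_tsv,
    write_histogram_tsv,
    write_paired_fasta,
    write_pair_table,
    write_pairs_tsv,
    write_profile_tsv,
)
from .pairing import (
    NoOrfError,
    OrthologPair,
    TranscriptSet,
    extract_cds,
    filter_sequences,
    find_single_copy_pairs,
)
from .profiles import SelectionProfile, build_profile, filter_estimates, ks_histogram
from .rates import (
    SaturationError,
    SubstitutionEstimate,
    UndefinedRateError,
    estimate_ng86,
    estimate_yn00,
)

logger = logging.getLogger(__name__)


@dataclass
class PairRunResult:
    config: RunConfig
    pairs: list[OrthologPair]
    alignments: list[CodonAlignment]
    estimates: list[SubstitutionEstimate]
    profile: SelectionProfile
    cluster_results: list[ClusterTestResult]
    paths: dict[str, Path] = field(default_factory=dict)


def _pair_by_id(
    ts_a: TranscriptSet, ts_b: TranscriptSet, cds_mode: str, min_orf_codons: int = 10
) -> list[OrthologPair]:
    """Pair records with identical ids across the two sets (pre-paired
    inputs such as simulated cohorts)."""
    seqs_b = dict(ts_b.records)
    pairs = []
    for sid, seq_a in ts_a.records:
        if sid not in seqs_b:
            continue
        seq_b = seqs_b[sid]
        if cds_mode == "extract":
            try:
                seq_a = extract_cds(seq_a, min_orf_codons=min_orf_codons)
                seq_b = extract_cds(seq_b, min_orf_codons=min_orf_codons)
            except NoOrfError as exc:
                logger.info("gene %s dropped: %s", sid, exc)
                continue
        pairs.append(
            OrthologPair(
                gene_id=sid, seq_a=seq_a, seq_b=seq_b,
                similarity_score=float("nan"), id_a=sid, id_b=sid,
            )
        )
    return pairs


def estimate_alignment(
    aln: CodonAlignment, estimator: str = "YN00", default_kappa: float = 2.0
) -> SubstitutionEstimate:
    if estimator == "NG86":
        return estimate_ng86(aln)
    return estimate_yn00(aln, default_kappa=default_kappa)


def estimate_alignments(
    alignments: list[CodonAlignment],
    estimator: str = "YN00",
    default_kappa: float = 2.0,
) -> list[SubstitutionEstimate]:
    """Per-gene estimates; genes whose estimate is undefined (saturation,
    no comparable sites) are dropped with a log line."""
    out = []
    for aln in alignments:
        try:
            out.append(estimate_alignment(aln, estimator, default_kappa))
        except (SaturationError, UndefinedRateError, ValueError) as exc:
            logger.info("estimation failed for %s: %s", aln.gene_id, exc)
    return out


def cluster_candidate_tests(
    alignments: dict[str, CodonAlignment],
    estimates: list[SubstitutionEstimate],
    ratio_threshold: float = 2.0,
    n_perm: int = 999,
    seed: int = 0,
) -> list[ClusterTestResult]:
    """Run the clustered-substitution test on every filtered gene whose
    Ka/Ks exceeds the threshold.  Per-gene seeds are derived from the root
    seed so reruns are reproducible and gene order does not matter."""
    candidates = [
        e for e in filter_estimates(estimates) if e.ratio > ratio_threshold
    ]
    results = []
    for e in sorted(candidates, key=lambda e: e.gene_id):
        aln = alignments.get(e.gene_id)
        if aln is None:
            continue
        m = substitution_positions(aln)
        if m.k < 2:
            logger.info("cluster test skipped for %s: k=%d", e.gene_id, m.k)
            continue
        gene_tag = zlib.crc32(e.gene_id.encode())  # stable across processes
        gene_seed = int(
            np.random.SeedSequence([seed, gene_tag]).generate_state(1)[0] % (2**31)
        )
        results.append(cluster_test(m, n_perm=n_perm, seed=gene_seed))
    return results


def run_pair(config: RunConfig) -> PairRunResult:
    """Execute pairing -> alignment -> estimation -> filtering -> profile ->
    cluster tests for one taxon pair, writing all outputs plus a
    machine-readable run log."""
    for label, path in (("fasta_a", config.fasta_a), ("fasta_b", config.fasta_b)):
        if not Path(path).is_file():
            raise FileNotFoundError(f"{label} input not found: {path}")
    ts_a = TranscriptSet("a", read_fasta(config.fasta_a))
    ts_b = TranscriptSet("b", read_fasta(config.fasta_b))
    n_raw = (len(ts_a), len(ts_b))
    ts_a = filter_sequences(ts_a, config.min_len, config.max_stop_frac)
    ts_b = filter_sequences(ts_b, config.min_len, config.max_stop_frac)

    if config.pairing == "rbh":
        pairs = find_single_copy_pairs(
            ts_a, ts_b, min_score=config.min_score, cds_mode=config.cds_mode
        )
    else:
        pairs = _pair_by_id(ts_a, ts_b, config.cds_mode)

    alignments = [align_codons(p) for p in pairs]
    estimates = estimate_alignments(
        alignments, estimator=config.estimator, default_kappa=config.default_kappa
    )
    profile = build_profile(estimates, config.pair_id, bin_width=config.bin_width)
    aln_by_id = {a.gene_id: a for a in alignments}
    clusters = cluster_candidate_tests(
        aln_by_id,
        estimates,
        ratio_threshold=config.cluster_ratio_threshold,
        n_perm=config.n_perm,
        seed=config.seed,
    )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = config.pair_id
    paths = {
        "pairs": out_dir / f"{prefix}.pairs.tsv",
        "alignments": out_dir / f"{prefix}.alignments.fasta",
        "estimates": out_dir / f"{prefix}.estimates.tsv",
        "profile": out_dir / f"{prefix}.profile.tsv",
        "histogram": out_dir / f"{prefix}.ks_histogram.tsv",
        "clusters": out_dir / f"{prefix}.clusters.tsv",
        "log": out_dir / f"{prefix}.run_log.json",
    }
    write_pairs_tsv(pairs, paths["pairs"])
    write_paired_fasta(alignments, paths["alignments"])
    write_estimates_tsv(estimates, paths["estimates"])
    write_profile_tsv([profile], paths["profile"])
    write_histogram_tsv(
        ks_histogram(filter_estimates(estimates), config.bin_width), paths["histogram"]
    )
    write_cluster_tsv(clusters, paths["clusters"])

    log = {
        "version": __version__,
        "config": json.loads(json.dumps(config.__dict__, default=str)),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": {
            "transcripts_raw": n_raw,
            "transcripts_filtered": (len(ts_a), len(ts_b)),
            "pairs": len(pairs),
            "estimates": len(estimates),
            "filtered_estimates": profile.n_genes_filtered,
            "cluster_candidates": len(clusters),
        },
    }
    paths["log"].write_text(json.dumps(log, indent=2, sort_keys=True))
    return PairRunResult(
        config=config,
        pairs=pairs,
        alignments=alignments,
        estimates=estimates,
        profile=profile,
        cluster_results=clusters,
        paths=paths,
    )


def run_panel(
    records: list[TaxonPairRecord],
    shared_table: pd.DataFrame | None = None,
    times: dict[str, float] | None = None,
    out_dir=None,
    r_threshold: float = 0.5,
    ratio_cap: float | None = None,
) -> dict:
    """Cross-pair association panel (and optional shared-gene screen)."""
    if len(records) < 3:
        raise ValueError("need at least 3 taxon-pair records")
    associations = pair_level_associations(records)
    out = {"associations": associations}
    if shared_table is not None:
        if times is None:
            times = {r.pair_id: r.divergence_time_mya for r in records}
        screen, summary = gene_level_time_correlation(
            shared_table, times, r_threshold=r_threshold, ratio_cap=ratio_cap
        )
        out["screen"] = screen
        out["screen_summary"] = summary
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        associations.to_csv(out_dir / "associations.tsv", sep="\t", index=False)
        write_pair_table(records, out_dir / "pair_records.tsv")
        if "screen" in out:
            out["screen"].to_csv(out_dir / "screen.tsv", sep="\t", index=False)
            (out_dir / "screen_summary.json").write_text(
                json.dumps(out["screen_summary"], indent=2)
            )
    return out


def profile_simulated_pair(
    genes,
    pair_id: str,
    estimator: str = "YN00",
    bin_width: float = 0.01,
    align: bool = False,
) -> tuple[SelectionProfile, list[SubstitutionEstimate]]:
    """Estimate and profile a simulated cohort in memory.

    The default simulators are indel-free, so codon alignment is an
    identity operation; ``align=True`` runs it anyway (slower, used to
    exercise the full path)."""
    alignments = []
    for g in genes:
        if align:
            pair = OrthologPair(
                gene_id=g.gene_id, seq_a=g.cds_a, seq_b=g.cds_b,
                similarity_score=float("nan"), id_a=g.gene_id, id_b=g.gene_id,
            )
            alignments.append(align_codons(pair))
        else:
            alignments.append(
                CodonAlignment(
                    gene_id=g.gene_id,
                    aligned_a=g.cds_a,
                    aligned_b=g.cds_b,
                    n_codons_ungapped=len(g.cds_a) // 3,
                )
            )
    estimates = estimate_alignments(alignments, estimator=estimator)
    profile = build_profile(estimates, pair_id, bin_width=bin_width)
    return profile, estimates
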
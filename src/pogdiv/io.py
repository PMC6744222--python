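"""FASTA and TSV plumbing.

All tabular outputs have a header, a stable column order, and deterministic
row order (sorted by gene or pair id).  FASTA input is case-insensitive and
may be wrapped or unwrapped.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cluster import ClusterTestResult, SubstitutionMap
from .profiles import CATEGORIES, KsHistogram, SelectionProfile
from .rates import SubstitutionEstimate

ESTIMATE_COLUMNS = [
    "gene_id", "method", "Ka", "Ks", "Ka_Ks", "SE_Ka", "SE_Ks",
    "S", "N", "Sd", "Nd", "kappa", "n_codons",
]


def read_fasta(path) -> list[tuple[str, str]]:
    path = Path(path)
    records = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=sid, description="") for sid, seq in records),
        str(path),
        "fasta",
    )


def write_pairs_tsv(pairs, path) -> None:
    df = pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "id_a": p.id_a,
                "id_b": p.id_b,
                "score": p.similarity_score,
                "cds_len_a": len(p.seq_a),
                "cds_len_b": len(p.seq_b),
            }
            for p in sorted(pairs, key=lambda p: p.gene_id)
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_paired_fasta(alignments, path) -> None:
    """Aligned pairs as interleaved FASTA (two records per gene)."""
    records = []
    for aln in sorted(alignments, key=lambda a: a.gene_id):
        records.append((f"{aln.gene_id}|a", aln.aligned_a))
        records.append((f"{aln.gene_id}|b", aln.aligned_b))
    write_fasta(records, path)


def write_paml_pair(aln, handle) -> None:
    """Sequential PHYLIP-like paired alignment block (PAML input layout)."""
    handle.write(f" 2 {len(aln.aligned_a)}\n")
    handle.write(f"{aln.gene_id}_a\n{aln.aligned_a}\n")
    handle.write(f"{aln.gene_id}_b\n{aln.aligned_b}\n")


def write_estimates_tsv(estimates: list[SubstitutionEstimate], path) -> None:
    rows = [
        {
            "gene_id": e.gene_id,
            "method": e.method,
            "Ka": e.ka,
            "Ks": e.ks,
            "Ka_Ks": e.ratio,
            "SE_Ka": e.se_ka,
            "SE_Ks": e.se_ks,
            "S": e.s_sites,
            "N": e.n_sites,
            "Sd": e.sd,
            "Nd": e.nd,
            "kappa": e.kappa,
            "n_codons": e.n_codons,
        }
        for e in sorted(estimates, key=lambda e: e.gene_id)
    ]
    pd.DataFrame(rows, columns=ESTIMATE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_estimates_tsv(path) -> list[SubstitutionEstimate]:
    """Load a precomputed Ka/Ks table (profiling-only runs)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            SubstitutionEstimate(
                gene_id=str(row["gene_id"]),
                ka=float(row["Ka"]),
                ks=float(row["Ks"]),
                ratio=float(row["Ka_Ks"]) if pd.notna(row["Ka_Ks"]) else math.nan,
                se_ka=float(row.get("SE_Ka", math.nan)),
                se_ks=float(row.get("SE_Ks", math.nan)),
                s_sites=float(row.get("S", math.nan)),
                n_sites=float(row.get("N", math.nan)),
                sd=float(row.get("Sd", math.nan)),
                nd=float(row.get("Nd", math.nan)),
                kappa=float(row.get("kappa", math.nan)),
                method=str(row.get("method", "NG86")),
                n_codons=int(row.get("n_codons", 0)),
            )
        )
    return out


def write_profile_tsv(profiles: list[SelectionProfile], path) -> None:
    rows = []
    for p in sorted(profiles, key=lambda p: p.pair_id):
        row = {
            "pair_id": p.pair_id,
            "n_raw": p.n_genes_raw,
            "n_filtered": p.n_genes_filtered,
            "peak_ks": p.peak_ks,
            "modified_peak_ks": p.modified_peak_ks,
        }
        for c in CATEGORIES:
            row[f"count_{c}"] = p.category_counts[c]
        for c in CATEGORIES:
            row[f"prop_{c}"] = p.category_props[c]
        row["prop_purifying_lt_0.9"] = p.prop_purifying
        row["prop_positive_ge_1"] = p.prop_positive_ge1
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_histogram_tsv(h: KsHistogram, path) -> None:
    df = pd.DataFrame(
        {
            "bin_lo": h.bin_edges[:-1],
            "bin_hi": h.bin_edges[1:],
            "count": h.counts,
            "proportion": h.proportions(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_cluster_tsv(results: list[ClusterTestResult], path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "k": r.k,
            "length": r.length,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "n_perm": r.n_perm,
            "seed": r.seed,
        }
        for r in sorted(results, key=lambda r: r.gene_id)
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "k", "length", "statistic", "p_value", "n_perm", "seed"]
    ).to_csv(path, sep="\t", index=False)


def read_positions_file(path) -> list[SubstitutionMap]:
    """Precomputed substitution maps, one gene per line:
    ``gene_id<TAB>length<TAB>comma-separated positions``."""
    maps = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gene_id, length, pos = line.split("\t")
        positions = [int(p) for p in pos.split(",")] if pos else []
        maps.append(
            SubstitutionMap(gene_id=gene_id, length=int(length), positions=positions)
        )
    return maps


def read_pair_table(path):
    """Cross-pair record table: pair_id, divergence_time_mya, peak_ks,
    modified_peak_ks, prop_<category> columns (and optional
    prop_positive_ge_1)."""
    from .associations import TaxonPairRecord

    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        props = {c: float(row[f"prop_{c}"]) for c in CATEGORIES if f"prop_{c}" in row}
        records.append(
            TaxonPairRecord(
                pair_id=str(row["pair_id"]),
                divergence_time_mya=float(row["divergence_time_mya"]),
                peak_ks=float(row["peak_ks"]),
                modified_peak_ks=float(row.get("modified_peak_ks", row["peak_ks"])),
                category_props=props,
                prop_positive_ge1=float(row.get("prop_positive_ge_1", math.nan)),
            )
        )
    return records


def write_pair_table(records, path) -> None:
    rows = []
    for r in sorted(records, key=lambda r: r.pair_id):
        row = {
            "pair_id": r.pair_id,
            "divergence_time_mya": r.divergence_time_mya,
            "peak_ks": r.peak_ks,
            "modified_peak_ks": r.modified_peak_ks,
        }
        for c in CATEGORIES:
            row[f"prop_{c}"] = r.category_props.get(c, math.nan)
        row["prop_positive_ge_1"] = r.prop_positive_ge1
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cohort(genes, out_dir, pair_id: str) -> dict[str, Path]:
    """Write a simulated cohort as two FASTA files plus a ground-truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta_a": out_dir / f"{pair_id}_a.fasta",
        "fasta_b": out_dir / f"{pair_id}_b.fasta",
        "truth": out_dir / f"{pair_id}_truth.tsv",
    }
    write_fasta([(g.gene_id, g.cds_a) for g in genes], paths["fasta_a"])
    write_fasta([(g.gene_id, g.cds_b) for g in genes], paths["fasta_b"])
    truth = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "omega": g.omega,
                "t": g.t,
                "category": g.category,
                "clustered": int(g.clustered),
                "n_syn_events": g.n_syn_events,
                "n_nonsyn_events": g.n_nonsyn_events,
            }
            for g in genes
        ]
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
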
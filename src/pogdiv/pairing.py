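"""Transcript filtering, CDS extraction, and reciprocal-best-hit pairing.

From two assembled transcript sets, produce putatively single-copy ortholog
pairs: low-quality transcripts are removed by length and stop-codon
content, each cross-set transcript is matched by a deterministic similarity
scorer (shared k-mer prefilter followed by local nucleotide alignment), and
only reciprocal best hits are kept — for a two-taxon comparison this yields
exactly the "one gene from each taxon" groups the downstream rate
estimation consumes.  Coding regions are taken as the longest open reading
frame over all six frames (a pass-through mode accepts inputs that are
already CDS).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

DEFAULT_MIN_LEN = 30
DEFAULT_MAX_STOP_FRAC = 0.20
DEFAULT_MIN_ORF_CODONS = 10


class NoOrfError(ValueError):
    """No open reading frame of the required length in any frame."""


@dataclass
class TranscriptSet:
    """Post-assembly transcripts of one taxon."""

    taxon_id: str
    records: list[tuple[str, str]]  # (seq_id, nucleotide sequence)

    def __post_init__(self):
        ids = [sid for sid, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate seq_ids in transcript set {self.taxon_id!r}")
        if any(not seq for _, seq in self.records):
            raise ValueError("empty sequence in transcript set")
        self.records = [(sid, seq.upper()) for sid, seq in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class OrthologPair:
    """One putatively single-copy ortholog: a CDS from each taxon."""

    gene_id: str
    seq_a: str
    seq_b: str
    similarity_score: float
    id_a: str = ""
    id_b: str = ""

    def __post_init__(self):
        # a terminal stop codon is tolerated on input and trimmed
        for attr in ("seq_a", "seq_b"):
            seq = getattr(self, attr).upper()
            if len(seq) % 3 != 0:
                raise ValueError(f"{attr} length is not a multiple of 3")
            if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
                seq = seq[:-3]
            if any(seq[i: i + 3] in STOP_CODONS for i in range(0, len(seq), 3)):
                raise ValueError(f"internal stop codon in {attr}")
            setattr(self, attr, seq)


def _stop_fraction_frame0(seq: str) -> float:
    """Fraction of stop codons scanning complete frame-0 codons."""
    n_codons = len(seq) // 3
    if n_codons == 0:
        return 0.0
    stops = sum(
        1 for i in range(0, 3 * n_codons, 3) if seq[i: i + 3] in STOP_CODONS
    )
    return stops / n_codons


def filter_sequences(
    ts: TranscriptSet,
    min_len: int = DEFAULT_MIN_LEN,
    max_stop_frac: float = DEFAULT_MAX_STOP_FRAC,
) -> TranscriptSet:
    """Remove transcripts shorter than ``min_len`` nt or with a frame-0
    stop-codon fraction above ``max_stop_frac``; input order is kept."""
    if min_len < 3:
        raise ValueError("min_len must be at least 3")
    if not 0.0 <= max_stop_frac <= 1.0:
        raise ValueError("max_stop_frac must be in [0, 1]")
    kept = [
        (sid, seq)
        for sid, seq in ts.records
        if len(seq) >= min_len and _stop_fraction_frame0(seq) <= max_stop_frac
    ]
    if ts.records and not kept:
        warnings.warn(
            f"all transcripts of {ts.taxon_id!r} removed by filtering", stacklevel=2
        )
    return TranscriptSet(taxon_id=ts.taxon_id, records=kept)


def _orfs_in_frame(seq: str) -> list[tuple[int, str]]:
    """Maximal stop-free runs of unambiguous codons in frame 0 of ``seq``;
    returns (start_offset, run) pairs."""
    runs = []
    start = None
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i: 3 * i + 3]
        breaker = codon in STOP_CODONS or any(c not in "ACGT" for c in codon)
        if breaker:
            if start is not None:
                runs.append((3 * start, seq[3 * start: 3 * i]))
                start = None
        elif start is None:
            start = i
    if start is not None:
        runs.append((3 * start, seq[3 * start: 3 * n_codons]))
    return runs


def extract_cds(transcript: str, min_orf_codons: int = DEFAULT_MIN_ORF_CODONS) -> str:
    """Longest open reading frame over the six frames of a transcript.

    An ORF is a maximal run of unambiguous non-stop codons (a terminal stop
    is excluded; a frame with no stop yields the whole frame).  Ties are
    broken deterministically: longest first, then forward strand before
    reverse, lower frame offset, earlier position.
    """
    transcript = transcript.upper()
    if len(transcript) < 3:
        raise NoOrfError("transcript shorter than one codon")
    candidates = []  # (-length, strand, frame, start, run)
    for strand, seq in ((0, transcript), (1, str(Seq(transcript).reverse_complement()))):
        for frame in range(3):
            for start, run in _orfs_in_frame(seq[frame:]):
                candidates.append((-len(run), strand, frame, start, run))
    candidates.sort(key=lambda c: c[:4])
    if not candidates or len(candidates[0][4]) < 3 * min_orf_codons:
        raise NoOrfError(
            f"no ORF of >= {min_orf_codons} codons in any frame"
        )
    return candidates[0][4]


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i: i + k] for i in range(len(seq) - k + 1)}


def similarity_score(
    seq_x: str,
    seq_y: str,
    k: int = 8,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Deterministic similarity: 0 unless the sequences share a k-mer, else
    the local nucleotide alignment score."""
    if not (_kmer_set(seq_x, k) & _kmer_set(seq_y, k)):
        return 0.0
    if aligner is None:
        aligner = _nucleotide_aligner()
    return float(aligner.score(seq_x, seq_y))


def _nucleotide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def find_single_copy_pairs(
    ts_a: TranscriptSet,
    ts_b: TranscriptSet,
    min_score: float = 50.0,
    cds_mode: str = "extract",
    min_orf_codons: int = DEFAULT_MIN_ORF_CODONS,
) -> list[OrthologPair]:
    """Reciprocal best hits between two (filtered) transcript sets.

    A pair (x, y) is kept when y is x's best-scoring match in ``ts_b`` AND x
    is y's best in ``ts_a`` AND the score reaches ``min_score``; score ties
    are broken lexicographically by seq_id, so the result is deterministic
    and symmetric in its arguments.  ``cds_mode="extract"`` runs longest-ORF
    extraction on both members (pairs without a usable ORF are dropped with
    a log line); ``cds_mode="passthrough"`` expects the transcripts to be
    in-frame CDS already.
    """
    if cds_mode not in ("extract", "passthrough"):
        raise ValueError(f"unknown cds_mode {cds_mode!r}")
    aligner = _nucleotide_aligner()
    scores: dict[tuple[str, str], float] = {}
    for id_x, seq_x in ts_a.records:
        for id_y, seq_y in ts_b.records:
            s = similarity_score(seq_x, seq_y, aligner=aligner)
            if s >= min_score:
                scores[(id_x, id_y)] = s

    def best_hits(ids, other_axis):
        best: dict[str, str] = {}
        for this_id in ids:
            hits = [
                (key[other_axis], s)
                for key, s in scores.items()
                if key[1 - other_axis] == this_id
            ]
            if hits:
                # highest score; ties to the lexicographically smallest id
                hits.sort(key=lambda h: (-h[1], h[0]))
                best[this_id] = hits[0][0]
        return best

    best_in_b = best_hits([sid for sid, _ in ts_a.records], other_axis=1)
    best_in_a = best_hits([sid for sid, _ in ts_b.records], other_axis=0)

    seqs_a = dict(ts_a.records)
    seqs_b = dict(ts_b.records)
    pairs: list[OrthologPair] = []
    for id_x in sorted(best_in_b):
        id_y = best_in_b[id_x]
        if best_in_a.get(id_y) != id_x:
            continue
        seq_x, seq_y = seqs_a[id_x], seqs_b[id_y]
        if cds_mode == "extract":
            try:
                seq_x = extract_cds(seq_x, min_orf_codons=min_orf_codons)
                seq_y = extract_cds(seq_y, min_orf_codons=min_orf_codons)
            except NoOrfError as exc:
                logger.info("pair (%s, %s) dropped: %s", id_x, id_y, exc)
                continue
        pairs.append(
            OrthologPair(
                gene_id=f"{id_x}|{id_y}",
                seq_a=seq_x,
                seq_b=seq_y,
                similarity_score=scores[(id_x, id_y)],
                id_a=id_x,
                id_b=id_y,
            )
        )
    return pairs
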
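"""Codon-aware pairwise alignment.

The two coding sequences of an ortholog pair are aligned at the protein
level (global alignment, BLOSUM62, affine gap penalties) and the gap
pattern is threaded back onto the codons, so gaps always occur in
whole-codon units and the reading frame is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .pairing import OrthologPair

DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -0.5


@dataclass
class CodonAlignment:
    """Gap-threaded pair of in-frame coding sequences."""

    gene_id: str
    aligned_a: str
    aligned_b: str
    n_codons_ungapped: int

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.aligned_a) % 3 != 0:
            raise ValueError("alignment length is not a multiple of 3")
        for seq in (self.aligned_a, self.aligned_b):
            for i in range(0, len(seq), 3):
                codon = seq[i: i + 3]
                if "-" in codon and codon != "---":
                    raise ValueError("gap not in whole-codon units")

    def strip_gap_columns(self) -> tuple[str, str]:
        """Equal-length in-frame subsequences with all gap codons removed."""
        a_out, b_out = [], []
        for i in range(0, len(self.aligned_a), 3):
            ca = self.aligned_a[i: i + 3]
            cb = self.aligned_b[i: i + 3]
            if ca != "---" and cb != "---":
                a_out.append(ca)
                b_out.append(cb)
        return "".join(a_out), "".join(b_out)


def _protein_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_codons(
    pair: OrthologPair,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> CodonAlignment:
    """Protein-guided global codon alignment of an ortholog pair.

    The optimal-score alignment is unique up to traceback ties, which are
    resolved by the aligner's canonical traceback order, so the result is
    deterministic for given inputs and penalties.
    """
    prot_a = str(Seq(pair.seq_a).translate())
    prot_b = str(Seq(pair.seq_b).translate())
    if not prot_a or not prot_b:
        raise ValueError(f"zero-length translation for {pair.gene_id}")
    if "*" in prot_a or "*" in prot_b:
        raise ValueError(f"internal stop codon in {pair.gene_id}")

    aligner = _protein_aligner(gap_open, gap_extend)
    alignment = aligner.align(prot_a, prot_b)[0]
    aln_a, aln_b = str(alignment[0]), str(alignment[1])

    out_a, out_b = [], []
    ia = ib = 0
    for ra, rb in zip(aln_a, aln_b):
        if ra == "-":
            out_a.append("---")
        else:
            out_a.append(pair.seq_a[3 * ia: 3 * ia + 3])
            ia += 1
        if rb == "-":
            out_b.append("---")
        else:
            out_b.append(pair.seq_b[3 * ib: 3 * ib + 3])
            ib += 1
    aligned_a = "".join(out_a)
    aligned_b = "".join(out_b)
    n_ungapped = sum(
        1
        for i in range(0, len(aligned_a), 3)
        if aligned_a[i: i + 3] != "---" and aligned_b[i: i + 3] != "---"
    )
    return CodonAlignment(
        gene_id=pair.gene_id,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        n_codons_ungapped=n_ungapped,
    )
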
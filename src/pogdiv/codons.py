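"""Genetic-code tables and codon-level counting primitives.

Everything downstream (site counting, pathway-averaged difference counting,
the codon substitution simulator) works on integer-encoded sense codons.
The standard nuclear genetic code (NCBI table 1) is used throughout; all
study taxa are angiosperm nuclear transcriptomes.

Conventions fixed here and documented in docs/methods.md:

* Mutations that create a stop codon are counted as nonsynonymous in site
  counting, so the synonymous + nonsynonymous site totals per codon always
  sum to 3.
* Substitution pathways between codons differing at >1 position are
  enumerated over all orderings of the differing positions; pathways that
  pass through a stop codon are excluded.  If every ordering is blocked by
  a stop (rare), all orderings are used and steps touching a stop are
  scored as nonsynonymous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

NUCS = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

_standard = _BioCodonTable.unambiguous_dna_by_id[1]

ALL_CODONS = tuple(a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG")
STOP_CODONS = tuple(sorted(_standard.stop_codons))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in _standard.stop_codons)
N_SENSE = len(SENSE_CODONS)  # 61 under the standard code
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACIDS = tuple(_standard.forward_table[c] for c in SENSE_CODONS)

#: transitions are A<->G and C<->T
_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(n1: str, n2: str) -> bool:
    return (n1, n2) in _TRANSITION


def is_stop(codon: str) -> bool:
    return codon in _standard.stop_codons


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    if codon in _standard.stop_codons:
        return "*"
    return _standard.forward_table[codon]


def _mutants(codon: str, pos: int) -> list[str]:
    return [codon[:pos] + n + codon[pos + 1:] for n in NUCS if n != codon[pos]]


def _build_syn_counts() -> np.ndarray:
    """(61, 3) array: number of the 3 single-nt mutants at each position
    that are sense codons encoding the same amino acid."""
    out = np.zeros((N_SENSE, 3), dtype=np.int64)
    for i, codon in enumerate(SENSE_CODONS):
        aa = translate_codon(codon)
        for pos in range(3):
            out[i, pos] = sum(
                1
                for m in _mutants(codon, pos)
                if not is_stop(m) and translate_codon(m) == aa
            )
    return out


SYN_COUNTS = _build_syn_counts()

#: per-codon NG86 synonymous site count  (sum over positions of n_syn/3)
NG86_S_PER_CODON = SYN_COUNTS.sum(axis=1) / 3.0

#: degeneracy classes used for kappa estimation
FOURFOLD_POS = SYN_COUNTS == 3
NONDEG_POS = SYN_COUNTS == 0


@dataclass(frozen=True)
class GeneticCode:
    """Sense-codon translation map plus per-codon/position synonymous
    fractions — the degeneracy bookkeeping the S/N counters consume."""

    code_id: int = 1
    codon_to_aa: dict = field(default_factory=lambda: dict(zip(SENSE_CODONS, AMINO_ACIDS)))
    syn_fraction: np.ndarray = field(default_factory=lambda: SYN_COUNTS / 3.0)

    def __post_init__(self):
        assert len(self.codon_to_aa) == 61
        assert np.all(self.syn_fraction >= 0) and np.all(self.syn_fraction <= 1)


def encode_codons(cds: str) -> np.ndarray:
    """Encode an in-frame CDS (no stops, no ambiguity) as sense-codon indices."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length is not a multiple of 3")
    cds = cds.upper()
    try:
        return np.array(
            [CODON_INDEX[cds[i: i + 3]] for i in range(0, len(cds), 3)],
            dtype=np.int64,
        )
    except KeyError as exc:  # stop codon or ambiguous base
        raise ValueError(f"non-sense codon in CDS: {exc.args[0]}") from exc


def decode_codons(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


def pathway_step_counts(
    x: str,
    y: str,
    kappa: float = 1.0,
    omega: float = 1.0,
    pi: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """Pathway-averaged substitution step counts between two sense codons.

    Returns (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv): the expected number of
    synonymous/nonsynonymous transition/transversion steps on a minimal
    mutational path from ``x`` to ``y``, averaged over the orderings of the
    differing positions.  With ``kappa=omega=1`` and uniform ``pi`` every
    valid ordering gets equal weight — the NG86 convention.  Otherwise each
    ordering is weighted by the product over its steps of
    ``kappa^is_transition * omega^is_nonsynonymous * pi[target]``, which is
    how the YN00-style estimator biases ambiguous pathways.

    Symmetrised over direction so that (x, y) and (y, x) agree.
    """
    fwd = _directed_pathway(x, y, kappa, omega, pi)
    if kappa == 1.0 and omega == 1.0 and pi is None:
        return fwd  # equal weights are direction-symmetric already
    rev = _directed_pathway(y, x, kappa, omega, pi)
    return tuple((a + b) / 2.0 for a, b in zip(fwd, rev))


def _directed_pathway(x, y, kappa, omega, pi):
    diff = [i for i in range(3) if x[i] != y[i]]
    if not diff:
        return (0.0, 0.0, 0.0, 0.0)

    def walk(order, allow_stops):
        weight = 1.0
        steps = []
        cur = x
        for pos in order:
            nxt = cur[:pos] + y[pos] + cur[pos + 1:]
            if is_stop(nxt) and nxt != y and not allow_stops:
                return None
            ts = is_transition(cur[pos], y[pos])
            if is_stop(cur) or is_stop(nxt):
                syn = False
            else:
                syn = translate_codon(cur) == translate_codon(nxt)
            weight *= (kappa if ts else 1.0) * (1.0 if syn else omega)
            if pi is not None and not is_stop(nxt):
                weight *= pi[CODON_INDEX[nxt]]
            steps.append((syn, ts))
            cur = nxt
        return weight, steps

    orders = list(permutations(diff))
    walked = [walk(o, allow_stops=False) for o in orders]
    walked = [w for w in walked if w is not None]
    if not walked:  # every ordering passes through a stop codon
        walked = [walk(o, allow_stops=True) for o in orders]

    total_w = sum(w for w, _ in walked)
    if total_w <= 0.0:  # degenerate weights; fall back to equal weighting
        total_w = float(len(walked))
        walked = [(1.0, s) for _, s in walked]
    out = [0.0, 0.0, 0.0, 0.0]
    for w, steps in walked:
        for syn, ts in steps:
            k = (0 if syn else 2) + (0 if ts else 1)
            out[k] += w / total_w
    return tuple(out)


_NG86_TABLES: tuple[np.ndarray, np.ndarray] | None = None


def ng86_difference_tables() -> tuple[np.ndarray, np.ndarray]:
    """(61, 61) lookup tables of pathway-averaged synonymous (Sd) and
    nonsynonymous (Nd) difference counts under equal pathway weighting."""
    global _NG86_TABLES
    if _NG86_TABLES is None:
        sd = np.zeros((N_SENSE, N_SENSE))
        nd = np.zeros((N_SENSE, N_SENSE))
        for i, x in enumerate(SENSE_CODONS):
            for j in range(i + 1, N_SENSE):
                s_ts, s_tv, n_ts, n_tv = pathway_step_counts(x, SENSE_CODONS[j])
                sd[i, j] = sd[j, i] = s_ts + s_tv
                nd[i, j] = nd[j, i] = n_ts + n_tv
        _NG86_TABLES = (sd, nd)
    return _NG86_TABLES


def yn00_site_fractions(kappa: float, pi: np.ndarray | None = None) -> np.ndarray:
    """(61, 3) synonymous site fractions with transition/transversion and
    codon-frequency weighting.

    Each of a codon's three positions contributes one site, split between
    the synonymous and nonsynonymous classes in proportion to the weighted
    mutational opportunity ``kappa^is_transition * pi[target]``.  Mutations
    to stop codons stay in the denominator (weighted by the mean sense-codon
    frequency) so the split reduces exactly to the NG86 n_syn/3 fractions
    when kappa = 1 and codon usage is uniform.
    """
    if pi is None:
        pi = np.full(N_SENSE, 1.0 / N_SENSE)
    pi_bar = float(pi.mean())
    out = np.zeros((N_SENSE, 3))
    for i, codon in enumerate(SENSE_CODONS):
        aa = translate_codon(codon)
        for pos in range(3):
            w_syn = 0.0
            w_all = 0.0
            for m in _mutants(codon, pos):
                w = kappa if is_transition(codon[pos], m[pos]) else 1.0
                if is_stop(m):
                    w *= pi_bar
                else:
                    w *= pi[CODON_INDEX[m]]
                    if translate_codon(m) == aa:
                        w_syn += w
                w_all += w
            out[i, pos] = w_syn / w_all if w_all > 0 else 0.0
    return out
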
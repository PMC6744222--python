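"""Pairwise synonymous/nonsynonymous substitution-rate estimation.

Two counting estimators over one in-frame codon alignment:

* NG86 — equal-weight site counting, pathway-averaged difference counting,
  Jukes–Cantor multiple-hit correction.  Serves as the within-package
  reference method.
* YN00-style — site counting weighted by the transition/transversion rate
  ratio (kappa) and F3x4 codon frequencies, pathway weighting that biases
  ambiguous multi-step codon differences by kappa, omega and target-codon
  frequency, and Kimura two-parameter multiple-hit corrections applied
  separately to the synonymous and nonsynonymous classes.  omega and the
  difference counts are iterated to convergence.  This is the primary
  estimator.

Both report Ka, Ks, their ratio, delta-method standard errors, and the raw
site/difference counts.  Ratio sentinels follow the convention the
downstream filters expect: Ks = 0 with Ka > 0 is reported as 99.0, and
Ks = Ka = 0 as NaN (undefined).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .codons import (
    CODON_INDEX,
    FOURFOLD_POS,
    N_SENSE,
    NG86_S_PER_CODON,
    NONDEG_POS,
    NUC_INDEX,
    SENSE_CODONS,
    encode_codons,
    is_transition,
    ng86_difference_tables,
    pathway_step_counts,
    yn00_site_fractions,
)

#: Ka/Ks reported when Ks = 0 but Ka > 0 (mirrors the ratio sentinel the
#: downstream filtering removes).
RATIO_SENTINEL = 99.0

DEFAULT_KAPPA = 2.0


class SaturationError(ValueError):
    """Observed proportion of differences too large for the distance
    correction (log argument non-positive)."""


class UndefinedRateError(ValueError):
    """No synonymous (or nonsynonymous) sites to normalise by."""


@dataclass
class SubstitutionEstimate:
    """Ka/Ks estimate for one gene pair."""

    gene_id: str
    ka: float
    ks: float
    ratio: float  # ka/ks, RATIO_SENTINEL, or NaN when 0/0
    se_ka: float
    se_ks: float
    s_sites: float  # S
    n_sites: float  # N
    sd: float  # synonymous differences Sd
    nd: float  # nonsynonymous differences Nd
    kappa: float
    method: str  # "NG86" or "YN00"
    n_codons: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.ratio) and self.ratio != RATIO_SENTINEL


def _aligned_pair_indices(aln) -> tuple[np.ndarray, np.ndarray]:
    """Sense-codon index arrays for the two sequences of a codon alignment,
    keeping only columns where both codons are unambiguous sense codons.

    Accepts anything with ``aligned_a``/``aligned_b`` (gap-threaded, equal
    length, whole-codon gaps) or a plain (cds_a, cds_b) tuple of equal-length
    in-frame strings.
    """
    if isinstance(aln, tuple):
        a, b = aln
    else:
        a, b = aln.aligned_a, aln.aligned_b
    if len(a) != len(b) or len(a) % 3 != 0:
        raise ValueError("aligned sequences must have equal length, a multiple of 3")
    ia, ib = [], []
    for k in range(0, len(a), 3):
        ca, cb = a[k: k + 3].upper(), b[k: k + 3].upper()
        if "-" in ca or "-" in cb:
            continue
        if ca not in CODON_INDEX or cb not in CODON_INDEX:
            if any(ch not in "ACGT" for ch in ca + cb):
                continue  # ambiguity: drop the column pairwise
            raise ValueError(f"internal stop codon in alignment: {ca}/{cb}")
        ia.append(CODON_INDEX[ca])
        ib.append(CODON_INDEX[cb])
    return np.array(ia, dtype=np.int64), np.array(ib, dtype=np.int64)


def count_sites_ng86(cds: str) -> tuple[float, float]:
    """NG86 synonymous (S) and nonsynonymous (N) site counts for one CDS.

    Position i of each codon contributes (synonymous single-nt changes)/3
    to S; everything else, including changes to stop codons, goes to N, so
    S + N = 3 * n_codons exactly.
    """
    idx = encode_codons(cds)
    s = float(NG86_S_PER_CODON[idx].sum())
    return s, 3.0 * len(idx) - s


def count_differences_ng86(aln) -> tuple[float, float]:
    """Pathway-averaged synonymous (Sd) and nonsynonymous (Nd) difference
    counts over the gap-stripped columns of a codon alignment."""
    ia, ib = _aligned_pair_indices(aln)
    sd_tab, nd_tab = ng86_difference_tables()
    return float(sd_tab[ia, ib].sum()), float(nd_tab[ia, ib].sum())


def _jc_correct(p: float, sites: float) -> tuple[float, float]:
    """Jukes–Cantor corrected distance and its delta-method variance."""
    if p == 0.0:
        return 0.0, 0.0
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        raise SaturationError(f"proportion of differences {p:.4f} >= 3/4")
    d = -0.75 * math.log(arg)
    var = 9.0 * p * (1.0 - p) / ((3.0 - 4.0 * p) ** 2 * sites)
    return d, var


def _k2p_correct(p_ts: float, q_tv: float, sites: float) -> tuple[float, float]:
    """Kimura two-parameter corrected distance (transition proportion P,
    transversion proportion Q) and its delta-method variance."""
    if p_ts == 0.0 and q_tv == 0.0:
        return 0.0, 0.0
    a1 = 1.0 - 2.0 * p_ts - q_tv
    a2 = 1.0 - 2.0 * q_tv
    if a1 <= 0.0 or a2 <= 0.0:
        raise SaturationError(
            f"transition/transversion proportions P={p_ts:.4f}, Q={q_tv:.4f} saturated"
        )
    d = -0.5 * math.log(a1) - 0.25 * math.log(a2)
    a = 1.0 / a1
    b = 0.5 * (1.0 / a1 + 1.0 / a2)
    var = (a * a * p_ts + b * b * q_tv - (a * p_ts + b * q_tv) ** 2) / sites
    return d, var


def _ratio(ka: float, ks: float) -> float:
    if ks > 0.0:
        return ka / ks
    return RATIO_SENTINEL if ka > 0.0 else math.nan


def estimate_ng86(aln, gene_id: str | None = None) -> SubstitutionEstimate:
    """NG86 Ka/Ks estimate for one codon alignment."""
    ia, ib = _aligned_pair_indices(aln)
    if len(ia) == 0:
        raise ValueError("no comparable codon columns in alignment")
    s_a = float(NG86_S_PER_CODON[ia].sum())
    s_b = float(NG86_S_PER_CODON[ib].sum())
    s_sites = 0.5 * (s_a + s_b)
    n_sites = 3.0 * len(ia) - s_sites
    if s_sites <= 0.0:
        raise UndefinedRateError("no synonymous sites in alignment")

    sd_tab, nd_tab = ng86_difference_tables()
    sd = float(sd_tab[ia, ib].sum())
    nd = float(nd_tab[ia, ib].sum())

    ks, var_ks = _jc_correct(sd / s_sites, s_sites)
    ka, var_ka = _jc_correct(nd / n_sites, n_sites)
    return SubstitutionEstimate(
        gene_id=gene_id or getattr(aln, "gene_id", ""),
        ka=ka,
        ks=ks,
        ratio=_ratio(ka, ks),
        se_ka=math.sqrt(var_ka),
        se_ks=math.sqrt(var_ks),
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        kappa=1.0,
        method="NG86",
        n_codons=len(ia),
    )


def estimate_kappa(aln, default_kappa: float = DEFAULT_KAPPA) -> float:
    """Transition/transversion rate ratio from fourfold-degenerate and
    nondegenerate codon positions, with K2P multiple-hit correction.

    Positions are used only where BOTH codons fall in the same degeneracy
    class at that position.  Within each class the corrected transition and
    transversion distance components give kappa = 2s/v; the two class
    estimates are combined weighted by their site counts.  With no usable
    differences (or saturated corrections) the configured default is
    returned with a warning.
    """
    ia, ib = _aligned_pair_indices(aln)
    counts = {"four": [0, 0, 0], "zero": [0, 0, 0]}  # sites, ts diffs, tv diffs
    for a_i, b_i in zip(ia, ib):
        ca, cb = SENSE_CODONS[a_i], SENSE_CODONS[b_i]
        for pos in range(3):
            if FOURFOLD_POS[a_i, pos] and FOURFOLD_POS[b_i, pos]:
                cls = "four"
            elif NONDEG_POS[a_i, pos] and NONDEG_POS[b_i, pos]:
                cls = "zero"
            else:
                continue
            counts[cls][0] += 1
            if ca[pos] != cb[pos]:
                if is_transition(ca[pos], cb[pos]):
                    counts[cls][1] += 1
                else:
                    counts[cls][2] += 1

    estimates = []
    for sites, n_ts, n_tv in counts.values():
        if sites == 0 or (n_ts == 0 and n_tv == 0):
            continue
        p, q = n_ts / sites, n_tv / sites
        a1 = 1.0 - 2.0 * p - q
        a2 = 1.0 - 2.0 * q
        if a1 <= 0.0 or a2 <= 0.0:
            continue
        s = -0.5 * math.log(a1) + 0.25 * math.log(a2)
        v = -0.5 * math.log(a2)
        if v <= 0.0:  # no transversions observed: kappa unbounded above
            estimates.append((sites, 99.0))
            continue
        estimates.append((sites, max(2.0 * s / v, 0.01)))
    if not estimates:
        warnings.warn(
            "no informative degenerate sites for kappa; using default "
            f"kappa={default_kappa}",
            stacklevel=2,
        )
        return default_kappa
    total = sum(w for w, _ in estimates)
    return min(max(sum(w * k for w, k in estimates) / total, 0.01), 99.0)


def _f3x4_frequencies(ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    """F3x4 sense-codon frequencies from the pooled codons of both
    sequences: product of position-specific nucleotide frequencies,
    renormalised over the 61 sense codons."""
    pos_freq = np.zeros((3, 4))
    for idx in (ia, ib):
        for i in idx:
            codon = SENSE_CODONS[i]
            for pos in range(3):
                pos_freq[pos, NUC_INDEX[codon[pos]]] += 1.0
    pos_freq += 0.5  # light pseudocount keeps all sense codons reachable
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, NUC_INDEX[c[0]]]
            * pos_freq[1, NUC_INDEX[c[1]]]
            * pos_freq[2, NUC_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def estimate_yn00(
    aln,
    gene_id: str | None = None,
    default_kappa: float = DEFAULT_KAPPA,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> SubstitutionEstimate:
    """YN00-style Ka/Ks estimate for one codon alignment.

    Procedure: estimate kappa from degenerate sites; build F3x4 codon
    frequencies from the pair; count synonymous/nonsynonymous sites with
    kappa- and frequency-weighted mutational opportunity; then iterate —
    pathway-weight the codon differences by (kappa, omega, frequencies),
    apply K2P corrections per class, update omega = Ka/Ks — until omega
    moves by less than ``tol`` or ``max_iter`` is reached.
    """
    ia, ib = _aligned_pair_indices(aln)
    if len(ia) == 0:
        raise ValueError("no comparable codon columns in alignment")
    n_codons = len(ia)
    kappa = estimate_kappa(aln, default_kappa=default_kappa)
    pi = _f3x4_frequencies(ia, ib)

    frac = yn00_site_fractions(kappa, pi)  # (61, 3) synonymous fractions
    s_per_codon = frac.sum(axis=1)
    s_sites = 0.5 * float(s_per_codon[ia].sum() + s_per_codon[ib].sum())
    n_sites = 3.0 * n_codons - s_sites
    if s_sites <= 0.0:
        raise UndefinedRateError("no synonymous sites in alignment")

    # distinct unordered codon pairs with multiplicities
    lo = np.minimum(ia, ib)
    hi = np.maximum(ia, ib)
    codes, mult = np.unique(lo * N_SENSE + hi, return_counts=True)
    pairs = [
        (SENSE_CODONS[c // N_SENSE], SENSE_CODONS[c % N_SENSE], m)
        for c, m in zip(codes, mult)
        if c // N_SENSE != c % N_SENSE
    ]

    omega = 1.0
    ka = ks = 0.0
    var_ka = var_ks = 0.0
    sd = nd = 0.0
    for _ in range(max_iter):
        s_ts = s_tv = n_ts = n_tv = 0.0
        for x, y, m in pairs:
            a, b, c, d = pathway_step_counts(x, y, kappa=kappa, omega=omega, pi=pi)
            s_ts += m * a
            s_tv += m * b
            n_ts += m * c
            n_tv += m * d
        sd, nd = s_ts + s_tv, n_ts + n_tv
        ks, var_ks = _k2p_correct(s_ts / s_sites, s_tv / s_sites, s_sites)
        ka, var_ka = _k2p_correct(n_ts / n_sites, n_tv / n_sites, n_sites)
        if ks <= 0.0:
            break
        new_omega = ka / ks
        if abs(new_omega - omega) < tol:
            omega = new_omega
            break
        omega = new_omega

    return SubstitutionEstimate(
        gene_id=gene_id or getattr(aln, "gene_id", ""),
        ka=ka,
        ks=ks,
        ratio=_ratio(ka, ks),
        se_ka=math.sqrt(var_ka),
        se_ks=math.sqrt(var_ks),
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        kappa=kappa,
        method="YN00",
        n_codons=n_codons,
    )
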
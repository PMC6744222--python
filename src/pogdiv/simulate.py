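"""Codon-pair, cohort, and taxon-pair-panel simulators.

The generator is first-class: every stage of the analysis is exercised on
data drawn from a continuous-time Markov codon model in which the rate of
the single-nucleotide change x -> y is proportional to

    kappa^[transition] * omega^[nonsynonymous] * pi[y]

over the 61 sense codons (stop codons are unreachable).  Branch lengths are
expressed in expected substitutions per codon summed over both branches
under the neutral (omega = 1) normalisation, so the target omega of a gene
is well defined independently of its selective regime.

A cohort draws each gene's selection category from a six-way mixture and
its omega uniformly from a per-category range; a panel of taxon pairs maps
divergence times (mya) to branch lengths through a single calibration
constant and drifts the category mixture with time so that the abundance
of moderately purified genes rises, and that of strongly purified genes
falls, with divergence time.

Every simulator records ground truth (omega, category, realised synonymous
and nonsynonymous event counts, event positions) so estimator-recovery and
cluster-test power can be checked against the event log rather than
against another estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .codons import (
    N_SENSE,
    SENSE_CODONS,
    decode_codons,
    is_transition,
    translate_codon,
)
from .profiles import CATEGORIES

# --------------------------------------------------------------------------
# neighbour structure of the sense-codon graph, built once

_NEIGH_TS = np.zeros((N_SENSE, N_SENSE), dtype=bool)
_NEIGH_SYN = np.zeros((N_SENSE, N_SENSE), dtype=bool)
_NEIGH_POS = np.full((N_SENSE, N_SENSE), -1, dtype=np.int64)
for _i, _x in enumerate(SENSE_CODONS):
    for _j, _y in enumerate(SENSE_CODONS):
        _d = [_p for _p in range(3) if _x[_p] != _y[_p]]
        if len(_d) == 1:
            _p = _d[0]
            _NEIGH_POS[_i, _j] = _p
            _NEIGH_TS[_i, _j] = is_transition(_x[_p], _y[_p])
            _NEIGH_SYN[_i, _j] = translate_codon(_x) == translate_codon(_y)
_IS_NEIGHBOUR = _NEIGH_POS >= 0


def _uniform_pi() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def build_rate_matrix(omega: float, kappa: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalised 61x61 generator of the codon model."""
    q = np.where(_IS_NEIGHBOUR, np.where(_NEIGH_TS, kappa, 1.0), 0.0)
    q = q * np.where(_NEIGH_SYN | ~_IS_NEIGHBOUR, 1.0, omega)
    q = q * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def neutral_rate(kappa: float, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time at omega = 1; the
    normalisation constant that defines the branch-length units."""
    q1 = build_rate_matrix(1.0, kappa, pi)
    return float(-(pi * np.diag(q1)).sum())


@dataclass(frozen=True)
class SimulationParams:
    """True parameters of one simulated codon pair."""

    n_codons: int = 500
    omega: float = 0.2
    kappa: float = 2.0
    #: expected substitutions per codon summed over both branches (omega=1 scale)
    t: float = 0.2
    codon_freqs: str = "uniform"  # "uniform" or "F1x4"
    base_freqs: tuple[float, float, float, float] | None = None  # T, C, A, G
    seed: int = 0

    def pi(self) -> np.ndarray:
        if self.codon_freqs == "uniform":
            return _uniform_pi()
        if self.codon_freqs == "F1x4":
            if self.base_freqs is None:
                raise ValueError("F1x4 codon frequencies need base_freqs")
            f = np.asarray(self.base_freqs, dtype=float)
            f = f / f.sum()
            nuc_index = {"T": 0, "C": 1, "A": 2, "G": 3}
            pi = np.array(
                [f[nuc_index[c[0]]] * f[nuc_index[c[1]]] * f[nuc_index[c[2]]] for c in SENSE_CODONS]
            )
            return pi / pi.sum()
        raise ValueError(f"unknown codon frequency model {self.codon_freqs!r}")


def _evolve_branch(
    states: np.ndarray,
    t_branch: float,
    q: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int, bool]]]:
    """Evolve codon states for one branch; returns the new states and the
    event log [(nucleotide position, codon index, synonymous?)]."""
    states = states.copy()
    exit_rates = -np.diag(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = q / exit_rates[:, np.newaxis]
    np.fill_diagonal(jump, 0.0)
    jump = np.nan_to_num(jump)
    cum_jump = np.cumsum(jump, axis=1)
    events: list[tuple[int, int, bool]] = []

    active = np.arange(len(states))
    t_rem = np.full(len(states), t_branch)
    while active.size:
        lam = exit_rates[states[active]]
        frozen = lam <= 0.0  # omega=0 codons with no synonymous exits are rare but possible
        wait = np.full(active.size, np.inf)
        if (~frozen).any():
            wait[~frozen] = rng.exponential(1.0 / lam[~frozen])
        jumping_mask = wait < t_rem[active]
        t_rem[active] -= np.where(np.isfinite(wait), wait, 0.0)
        jumping = active[jumping_mask]
        if jumping.size:
            u = rng.random(jumping.size)
            rows = cum_jump[states[jumping]]
            rows = rows / rows[:, -1:]
            nxt = (rows > u[:, np.newaxis]).argmax(axis=1)
            for codon_idx, old, new in zip(jumping, states[jumping], nxt):
                pos = 3 * int(codon_idx) + int(_NEIGH_POS[old, new])
                events.append((pos, int(codon_idx), bool(_NEIGH_SYN[old, new])))
            states[jumping] = nxt
        active = jumping
    return states, events


def simulate_codon_pair(p: SimulationParams) -> tuple[str, str, dict]:
    """Draw an ancestor from the stationary codon frequencies and evolve two
    independent branches of length t/2; returns (cds_a, cds_b, truth)."""
    rng = np.random.default_rng(p.seed)
    return _simulate_pair_with_rng(p, rng)


def _simulate_pair_with_rng(
    p: SimulationParams,
    rng: np.random.Generator,
    window: tuple[int, int] | None = None,
) -> tuple[str, str, dict]:
    """Core pair simulator.  With ``window=(start_codon, end_codon)`` all
    nonsynonymous change is confined to that codon window (omega inside is
    raised so that the gene-wide expected omega is unchanged)."""
    pi = p.pi()
    scale = neutral_rate(p.kappa, pi)
    ancestor = rng.choice(N_SENSE, size=p.n_codons, p=pi)

    if window is None:
        q = build_rate_matrix(p.omega, p.kappa, pi) / scale
        regimes = [(np.arange(p.n_codons), q)]
    else:
        lo, hi = window
        frac = (hi - lo) / p.n_codons
        q_in = build_rate_matrix(p.omega / frac, p.kappa, pi) / scale
        q_out = build_rate_matrix(0.0, p.kappa, pi) / scale
        inside = np.arange(lo, hi)
        outside = np.concatenate([np.arange(0, lo), np.arange(hi, p.n_codons)])
        regimes = [(inside, q_in), (outside, q_out)]

    seqs = []
    n_syn = n_nonsyn = 0
    positions: list[int] = []
    for _branch in range(2):
        states = ancestor.copy()
        for codon_set, q in regimes:
            if codon_set.size == 0:
                continue
            new, events = _evolve_branch(states[codon_set], p.t / 2.0, q, rng)
            states[codon_set] = new
            for pos, codon_local, syn in events:
                nt = 3 * int(codon_set[codon_local]) + pos % 3
                positions.append(nt)
                if syn:
                    n_syn += 1
                else:
                    n_nonsyn += 1
        seqs.append(decode_codons(states))

    truth = {
        "omega": p.omega,
        "kappa": p.kappa,
        "t": p.t,
        "n_codons": p.n_codons,
        "n_syn_events": n_syn,
        "n_nonsyn_events": n_nonsyn,
        "event_positions": sorted(positions),
        "window": window,
    }
    return seqs[0], seqs[1], truth


# --------------------------------------------------------------------------
# cohorts

#: default per-category omega sampling ranges (uniform draws)
DEFAULT_OMEGA_RANGES: dict[str, tuple[float, float]] = {
    "strong_purifying": (0.02, 0.08),
    "moderate_purifying": (0.15, 0.45),
    "relaxed_purifying": (0.55, 0.85),
    "near_neutral": (0.92, 1.08),
    "weak_positive": (1.2, 1.9),
    "strong_positive": (2.2, 5.0),
}

#: default category mixture, chosen inside the observed per-pair abundance
#: ranges so the canonical rank order is reproducible
DEFAULT_MIXTURE: dict[str, float] = {
    "strong_purifying": 0.25,
    "moderate_purifying": 0.50,
    "relaxed_purifying": 0.14,
    "near_neutral": 0.03,
    "weak_positive": 0.06,
    "strong_positive": 0.02,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters for one taxon pair's gene cohort."""

    n_genes: int = 2000
    category_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    omega_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OMEGA_RANGES)
    )
    #: branch length t of every gene (expected subs/codon over both branches)
    divergence_scale: float = 0.2
    #: fraction of strong-positive genes whose nonsynonymous changes are
    #: confined to a short window; most strongly selected genes in the study
    #: system show clustered substitutions, hence a majority default
    clustered_fraction: float = 0.7
    cluster_window_frac: float = 0.05
    n_codons: int = 500
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.category_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category mixture sums to {total}, not 1")


@dataclass
class SimulatedGene:
    gene_id: str
    cds_a: str
    cds_b: str
    omega: float
    t: float
    category: str
    clustered: bool
    n_syn_events: int
    n_nonsyn_events: int
    event_positions: list[int]


def simulate_cohort(spec: CohortSpec) -> list[SimulatedGene]:
    """Simulate a cohort of ortholog pairs under the category mixture."""
    rng = np.random.default_rng(spec.seed)
    mixture = np.array([spec.category_mixture[c] for c in CATEGORIES])
    cats = rng.choice(len(CATEGORIES), size=spec.n_genes, p=mixture)
    genes: list[SimulatedGene] = []
    for g in range(spec.n_genes):
        cat = CATEGORIES[cats[g]]
        lo, hi = spec.omega_ranges[cat]
        omega = float(rng.uniform(lo, hi))
        clustered = cat == "strong_positive" and rng.random() < spec.clustered_fraction
        window = None
        t_gene = spec.divergence_scale
        if clustered:
            w = max(int(round(spec.cluster_window_frac * spec.n_codons)), 2)
            start = int(rng.integers(0, spec.n_codons - w + 1))
            window = (start, start + w)
            # A ratio > 2 gene whose nonsynonymous changes all sit in a 5%
            # window can only carry a modest number of substitutions before
            # the window saturates and the signal becomes uncountable, so
            # clustered genes are low-divergence genes: cap the branch
            # length so the expected window density stays ~0.35 changes/nt.
            t_gene = min(t_gene, 1.4 * spec.cluster_window_frac / omega)
        params = SimulationParams(
            n_codons=spec.n_codons,
            omega=omega,
            kappa=spec.kappa,
            t=t_gene,
        )
        cds_a, cds_b, truth = _simulate_pair_with_rng(params, rng, window=window)
        genes.append(
            SimulatedGene(
                gene_id=f"g{g:06d}",
                cds_a=cds_a,
                cds_b=cds_b,
                omega=omega,
                t=t_gene,
                category=cat,
                clustered=clustered,
                n_syn_events=truth["n_syn_events"],
                n_nonsyn_events=truth["n_nonsyn_events"],
                event_positions=truth["event_positions"],
            )
        )
    return genes


# --------------------------------------------------------------------------
# multi-pair panels

#: default divergence-time window of the study taxa (mya)
DEFAULT_TIME_RANGE = (1.69, 10.67)

#: calibration: expected neutral substitutions per codon (both branches) per
#: million years of divergence; places peak Ks in the sub-0.1 range the
#: shallow angiosperm pairs show
DEFAULT_CALIBRATION = 0.015

#: mixtures at the youngest and oldest divergence times; linear interpolation
#: in between.  Moderate purifying rises with time, strong purifying falls,
#: and the positively selected share declines slightly.
EARLY_MIXTURE: dict[str, float] = {
    "strong_purifying": 0.34,
    "moderate_purifying": 0.41,
    "relaxed_purifying": 0.13,
    "near_neutral": 0.025,
    "weak_positive": 0.075,
    "strong_positive": 0.02,
}
LATE_MIXTURE: dict[str, float] = {
    "strong_purifying": 0.13,
    "moderate_purifying": 0.645,
    "relaxed_purifying": 0.15,
    "near_neutral": 0.018,
    "weak_positive": 0.045,
    "strong_positive": 0.012,
}


def drifted_mixture(time_mya: float, t_min: float, t_max: float) -> dict[str, float]:
    s = 0.0 if t_max <= t_min else (time_mya - t_min) / (t_max - t_min)
    s = min(max(s, 0.0), 1.0)
    mix = {c: (1 - s) * EARLY_MIXTURE[c] + s * LATE_MIXTURE[c] for c in CATEGORIES}
    total = sum(mix.values())
    return {c: v / total for c, v in mix.items()}


@dataclass
class SimulatedPair:
    pair_id: str
    divergence_time_mya: float
    t: float
    mixture: dict[str, float]
    genes: list[SimulatedGene]


def simulate_pair_panel(
    n_pairs: int = 20,
    times_mya: list[float] | None = None,
    calibration: float = DEFAULT_CALIBRATION,
    spec: CohortSpec | None = None,
    seed: int = 0,
    mixture_drift: bool = True,
) -> list[SimulatedPair]:
    """Simulate a panel of taxon pairs whose divergence times map to branch
    lengths via ``t = calibration * time`` and whose category mixtures drift
    with time (unless disabled)."""
    if times_mya is None:
        times_mya = list(np.linspace(*DEFAULT_TIME_RANGE, n_pairs))
    if len(times_mya) != n_pairs:
        raise ValueError("times_mya length must equal n_pairs")
    base = spec if spec is not None else CohortSpec()
    t_min, t_max = min(times_mya), max(times_mya)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_pairs) % (2**31)
    panel: list[SimulatedPair] = []
    for i, time in enumerate(times_mya):
        mixture = (
            drifted_mixture(time, t_min, t_max)
            if mixture_drift
            else dict(base.category_mixture)
        )
        pair_spec = replace(
            base,
            category_mixture=mixture,
            divergence_scale=calibration * time,
            seed=int(child_seeds[i]),
        )
        genes = simulate_cohort(pair_spec)
        panel.append(
            SimulatedPair(
                pair_id=f"pair{i:02d}",
                divergence_time_mya=float(time),
                t=calibration * time,
                mixture=mixture,
                genes=genes,
            )
        )
    return panel


def introduce_codon_indels(
    cds: str, n_deletions: int, rng: np.random.Generator
) -> str:
    """Delete ``n_deletions`` whole codons at random positions (alignment
    test helper; the default simulators are indel-free)."""
    n_codons = len(cds) // 3
    if n_deletions >= n_codons:
        raise ValueError("cannot delete every codon")
    drop = set(rng.choice(n_codons, size=n_deletions, replace=False).tolist())
    return "".join(
        cds[3 * i: 3 * i + 3] for i in range(n_codons) if i not in drop
    )
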
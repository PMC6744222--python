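"""Per-taxon-pair selection-pressure summaries.

Turns a list of per-gene Ka/Ks estimates into the quantities the cross-pair
analyses consume: the Ks histogram in 0.01-wide bins, the Ks value at peak
frequency (plain and with the adjacent-bin near-tie rule), and the
abundances of six Ka/Ks selection categories.

Category boundaries (documented, gap- and overlap-free):

* strong purifying      Ka/Ks < 0.1
* moderate purifying    0.1 <= Ka/Ks < 0.5
* relaxed purifying     0.5 <= Ka/Ks < 0.9
* near neutral          0.9 <= Ka/Ks <= 1.1
* weak/moderate positive 1.1 < Ka/Ks <= 2
* strong positive       Ka/Ks > 2
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .rates import RATIO_SENTINEL, SubstitutionEstimate

logger = logging.getLogger(__name__)

#: selection categories, ordered from strongest purifying to strongest positive
CATEGORIES = (
    "strong_purifying",
    "moderate_purifying",
    "relaxed_purifying",
    "near_neutral",
    "weak_positive",
    "strong_positive",
)

DEFAULT_BIN_WIDTH = 0.01

#: relative-difference threshold of the adjacent-bin near-tie rule
NEAR_TIE_FRACTION = 0.10


@dataclass
class KsHistogram:
    """Ks frequency distribution over half-open bins [lo, hi) of fixed width
    starting at 0; the last bin is closed at the maximum observed value."""

    bin_width: float
    bin_edges: np.ndarray  # length n_bins + 1
    counts: np.ndarray  # integer counts, length n_bins
    total: int

    def proportions(self) -> np.ndarray:
        return self.counts / self.total


@dataclass
class SelectionProfile:
    """Selection-pressure summary of one taxon pair."""

    pair_id: str
    n_genes_raw: int
    n_genes_filtered: int
    peak_ks: float
    modified_peak_ks: float
    category_counts: dict[str, int]
    category_props: dict[str, float]
    #: share of genes with Ka/Ks < 0.9 ("overall purifying")
    prop_purifying: float = 0.0
    #: share of genes with Ka/Ks >= 1.0 (putative positive selection)
    prop_positive_ge1: float = 0.0
    rank_order: tuple[str, ...] = field(default_factory=tuple)


def filter_estimates(
    estimates: list[SubstitutionEstimate],
) -> list[SubstitutionEstimate]:
    """Drop genes with Ks = 0 and genes carrying the Ka/Ks ratio sentinel
    (99) or an undefined (0/0) ratio; everything downstream uses the
    filtered list."""
    kept = [
        e
        for e in estimates
        if e.ks > 0.0 and math.isfinite(e.ratio) and e.ratio != RATIO_SENTINEL
    ]
    removed = len(estimates) - len(kept)
    if removed:
        logger.info("filter_estimates: removed %d of %d genes", removed, len(estimates))
    return kept


def ks_histogram(
    estimates: list[SubstitutionEstimate], bin_width: float = DEFAULT_BIN_WIDTH
) -> KsHistogram:
    """Bin the Ks values into half-open intervals [0, w), [w, 2w), ...

    A value falling exactly on an interior edge belongs to the upper bin;
    the last bin extends to the maximum observed Ks.
    """
    if not estimates:
        raise ValueError("cannot build a Ks histogram from zero estimates")
    ks = np.array([e.ks for e in estimates], dtype=float)
    n_bins = max(int(ks.max() // bin_width) + 1, 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(ks, bins=edges)
    return KsHistogram(
        bin_width=bin_width,
        bin_edges=edges,
        counts=counts.astype(np.int64),
        total=len(ks),
    )


def peak_ks(h: KsHistogram) -> float:
    """Midpoint of the modal Ks bin; ties go to the lowest tied bin (with a
    warning)."""
    if h.total < 1:
        raise ValueError("empty histogram")
    modal = int(np.argmax(h.counts))  # argmax takes the first = lowest bin
    if int((h.counts == h.counts[modal]).sum()) > 1:
        warnings.warn("tied modal Ks bins; using the lowest", stacklevel=2)
    return float(h.bin_edges[modal] + h.bin_width / 2.0)


def modified_peak_ks(h: KsHistogram) -> float:
    """Peak Ks with the adjacent-bin near-tie rule.

    If the modal bin and an immediate neighbour hold frequencies that differ
    by less than 10% of their combined frequency, the shared boundary of the
    two bins is returned instead of the modal midpoint (e.g. neighbouring
    bins at 21% and 19% of genes yield the boundary value).  When both
    neighbours qualify, the one closer in frequency wins.
    """
    if h.total < 1:
        raise ValueError("empty histogram")
    modal = int(np.argmax(h.counts))
    f_modal = h.counts[modal]
    candidates = []
    for nb in (modal - 1, modal + 1):
        if 0 <= nb < len(h.counts):
            f_nb = h.counts[nb]
            combined = f_modal + f_nb
            if combined > 0 and abs(int(f_modal) - int(f_nb)) < NEAR_TIE_FRACTION * combined:
                candidates.append((abs(int(f_modal) - int(f_nb)), nb))
    if not candidates:
        return peak_ks(h)
    _, nb = min(candidates)
    # shared boundary between the modal bin and the chosen neighbour
    return float(h.bin_edges[max(modal, nb)])


def classify_selection(ratio: float) -> str:
    """Map a defined Ka/Ks ratio to its selection category."""
    if not (ratio >= 0.0) or not math.isfinite(ratio):
        raise ValueError(f"undefined Ka/Ks ratio: {ratio!r}")
    if ratio < 0.1:
        return "strong_purifying"
    if ratio < 0.5:
        return "moderate_purifying"
    if ratio < 0.9:
        return "relaxed_purifying"
    if ratio <= 1.1:
        return "near_neutral"
    if ratio <= 2.0:
        return "weak_positive"
    return "strong_positive"


def build_profile(
    estimates: list[SubstitutionEstimate],
    pair_id: str,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> SelectionProfile:
    """Filter -> histogram -> peak statistics -> category abundances."""
    kept = filter_estimates(estimates)
    if not kept:
        raise ValueError(f"no estimates survive filtering for pair {pair_id!r}")
    h = ks_histogram(kept, bin_width=bin_width)
    counts = {c: 0 for c in CATEGORIES}
    n_purifying = 0
    n_ge1 = 0
    for e in kept:
        counts[classify_selection(e.ratio)] += 1
        if e.ratio < 0.9:
            n_purifying += 1
        if e.ratio >= 1.0:
            n_ge1 += 1
    n = len(kept)
    props = {c: counts[c] / n for c in CATEGORIES}
    # abundance rank order, most to least abundant; ties broken by the
    # canonical category order for determinism
    order = tuple(sorted(CATEGORIES, key=lambda c: (-counts[c], CATEGORIES.index(c))))
    return SelectionProfile(
        pair_id=pair_id,
        n_genes_raw=len(estimates),
        n_genes_filtered=n,
        peak_ks=peak_ks(h),
        modified_peak_ks=modified_peak_ks(h),
        category_counts=counts,
        category_props=props,
        prop_purifying=n_purifying / n,
        prop_positive_ge1=n_ge1 / n,
        rank_order=order,
    )
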
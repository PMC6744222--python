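"""Cross-pair and cross-gene correlation analyses.

Links each taxon pair's divergence time (mya) to its peak-Ks divergence
proxy and to the abundances of the selection categories, and screens
widely shared genes for monotone time trends in their Ka/Ks ratios.
Correlations are plain sample Pearson coefficients; two-sided p-values come
from the t-distribution with n-2 degrees of freedom.  The association panel
is reported raw (no multiple-testing correction), matching how such
cross-pair tables are usually presented.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CATEGORIES, SelectionProfile

logger = logging.getLogger(__name__)


@dataclass
class TaxonPairRecord:
    """One row of the cross-pair association table."""

    pair_id: str
    divergence_time_mya: float
    peak_ks: float
    modified_peak_ks: float
    category_props: dict[str, float]
    prop_positive_ge1: float = math.nan

    def __post_init__(self):
        if not self.divergence_time_mya > 0:
            raise ValueError(
                f"divergence time must be positive ({self.pair_id}: "
                f"{self.divergence_time_mya})"
            )
        for c, v in self.category_props.items():
            if math.isfinite(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"proportion out of range for {c}: {v}")

    @classmethod
    def from_profile(
        cls, profile: SelectionProfile, divergence_time_mya: float
    ) -> "TaxonPairRecord":
        return cls(
            pair_id=profile.pair_id,
            divergence_time_mya=divergence_time_mya,
            peak_ks=profile.peak_ks,
            modified_peak_ks=profile.modified_peak_ks,
            category_props=dict(profile.category_props),
            prop_positive_ge1=profile.prop_positive_ge1,
        )


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pair_level_associations(records: list[TaxonPairRecord]) -> pd.DataFrame:
    """The cross-pair correlation panel.

    Rows: time vs peak Ks; peak Ks vs each category abundance and vs the
    abundance of putative positive selection (Ka/Ks >= 1); time vs the
    moderate- and strong-purifying abundances.  Each peak-Ks row is also
    computed with the near-tie-modified peak Ks.  Output columns:
    x, y, n, r, p.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 taxon pairs")
    records = sorted(records, key=lambda r: r.pair_id)
    cols: dict[str, np.ndarray] = {
        "time": np.array([r.divergence_time_mya for r in records]),
        "peak_ks": np.array([r.peak_ks for r in records]),
        "modified_peak_ks": np.array([r.modified_peak_ks for r in records]),
    }
    for c in CATEGORIES:
        cols[c] = np.array([r.category_props.get(c, math.nan) for r in records])
    cols["positive_ge1"] = np.array([r.prop_positive_ge1 for r in records])

    panel = [("time", "peak_ks"), ("time", "modified_peak_ks")]
    for peak in ("peak_ks", "modified_peak_ks"):
        for c in (*CATEGORIES, "positive_ge1"):
            panel.append((peak, c))
    panel += [
        ("time", "moderate_purifying"),
        ("time", "strong_purifying"),
    ]

    rows = []
    for x_name, y_name in panel:
        x, y = cols[x_name], cols[y_name]
        ok = np.isfinite(x) & np.isfinite(y)
        try:
            r, p = pearson_r(x[ok], y[ok])
        except ValueError as exc:
            logger.warning("association %s ~ %s skipped: %s", y_name, x_name, exc)
            continue
        rows.append({"x": x_name, "y": y_name, "n": int(ok.sum()), "r": r, "p": p})
    return pd.DataFrame(rows, columns=["x", "y", "n", "r", "p"])


def gene_level_time_correlation(
    table: pd.DataFrame,
    times: dict[str, float],
    r_threshold: float = 0.5,
    ratio_cap: float | None = None,
    min_presence: float = 0.9,
    sentinel: float = 99.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Screen widely shared genes for time trends in Ka/Ks.

    ``table``: genes x pairs matrix of Ka/Ks ratios (NaN = gene absent in
    that pair); ``times``: divergence time per pair.  Genes present in fewer
    than ``min_presence`` of the pairs are dropped; ratios equal to 0 or to
    the sentinel are removed pairwise; with ``ratio_cap`` set, ratios at or
    above the cap are removed too.  Per gene, the Pearson r between time and
    ratio is computed over the remaining pairs (pairwise deletion; at least
    3 required).  Returns the per-gene table (gene_id, n, r, p, sign,
    passed) and summary counts of genes passing |r| > r_threshold by sign.
    """
    pair_ids = [p for p in table.columns if p in times]
    if len(pair_ids) < 3:
        raise ValueError("need at least 3 pairs with divergence times")
    t = np.array([times[p] for p in pair_ids])
    rows = []
    for gene_id, series in table[pair_ids].iterrows():
        vals = series.to_numpy(dtype=float)
        present = np.isfinite(vals)
        if present.sum() < min_presence * len(pair_ids):
            continue
        usable = present & (vals != 0.0) & (vals != sentinel)
        if ratio_cap is not None:
            usable &= vals < ratio_cap
        if usable.sum() < 3:
            logger.info("gene %s skipped: %d usable pairs", gene_id, usable.sum())
            continue
        try:
            r, p = pearson_r(t[usable], vals[usable])
        except ValueError:
            r, p = 0.0, 1.0  # constant ratios: no trend
        rows.append(
            {
                "gene_id": gene_id,
                "n": int(usable.sum()),
                "r": r,
                "p": p,
                "sign": "+" if r > 0 else "-",
                "passed": abs(r) > r_threshold,
            }
        )
    screen = pd.DataFrame(
        rows, columns=["gene_id", "n", "r", "p", "sign", "passed"]
    )
    passed = screen[screen["passed"]] if len(screen) else screen
    summary = {
        "n_genes": len(screen),
        "n_passed": int(len(passed)),
        "n_positive": int((passed["sign"] == "+").sum()) if len(screen) else 0,
        "n_negative": int((passed["sign"] == "-").sum()) if len(screen) else 0,
    }
    return screen, summary
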
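"""Co-mapping of microbial and metabolite QTL.

Two peaks co-map when they lie on the same chromosome, both exceed a relaxed
LOD threshold (default 6.1, the conventional P < 0.5 co-mapping level), and
their 95% Bayes support intervals intersect (closed intervals: touching
endpoints count, since the intervals are themselves approximate).  Founder
allele-effect patterns of co-mapping peaks are compared by the signed
Pearson correlation of their 8-vectors, so opposed patterns come out
negative.  A Spearman / Benjamini-Hochberg screen over trait pairs
complements the genetic overlap evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pleioscan.scan import QtlPeak


@dataclass
class CoMapPair:
    """A microbial and a metabolite peak with overlapping support."""

    peak_a: QtlPeak
    peak_b: QtlPeak
    overlap_lo: float
    overlap_hi: float
    r_effects: float | None = None

    def __post_init__(self) -> None:
        if self.peak_a.chromosome != self.peak_b.chromosome:
            raise ValueError("co-mapping peaks must share a chromosome")
        if self.overlap_lo > self.overlap_hi:
            raise ValueError("empty overlap interval")


def find_overlaps(
    peaks_a: list[QtlPeak],
    peaks_b: list[QtlPeak],
    lod_min: float = 6.1,
    compute_r: bool = True,
) -> list[CoMapPair]:
    """All (a, b) pairs on a common chromosome with intersecting closed
    support intervals and both LODs >= lod_min."""
    pairs: list[CoMapPair] = []
    for pa in peaks_a:
        if pa.lod < lod_min:
            continue
        for pb in peaks_b:
            if pb.lod < lod_min or pb.chromosome != pa.chromosome:
                continue
            lo = max(pa.ci_lo, pb.ci_lo)
            hi = min(pa.ci_hi, pb.ci_hi)
            if lo <= hi:
                r = None
                if compute_r and pa.coefs is not None and pb.coefs is not None:
                    try:
                        r = allele_effect_similarity(pa.coefs, pb.coefs)
                    except ValueError:
                        r = None
                pairs.append(CoMapPair(pa, pb, lo, hi, r))
    return pairs


def allele_effect_similarity(coefs_a: np.ndarray, coefs_b: np.ndarray) -> float:
    """Signed Pearson correlation of two 8-vectors of founder coefficients.

    +1 for identical allele-effect patterns, -1 for exactly opposed ones
    (e.g. a pair where the same founders push the two traits in opposite
    directions)."""
    a = np.asarray(coefs_a, dtype=float)
    b = np.asarray(coefs_b, dtype=float)
    if a.shape != (8,) or b.shape != (8,):
        raise ValueError("founder coefficient vectors must have length 8")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("allele-effect correlation undefined for a zero-variance vector")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CorrelationScreen:
    """Spearman correlations over trait pairs with BH-adjusted q values and
    the filter settings applied."""

    table: pd.DataFrame  # trait_a, trait_b, rho, p, q, pass
    q_cutoff: float
    abs_rho_cutoff: float


def spearman_bh_screen(
    traits_a: pd.DataFrame,
    traits_b: pd.DataFrame | None = None,
    q_cutoff: float = 0.01,
    abs_rho_cutoff: float = 0.35,
    min_pairs: int = 3,
) -> CorrelationScreen:
    """Spearman correlation screen with Benjamini-Hochberg adjustment.

    Correlates every column of ``traits_a`` with every column of ``traits_b``
    (or all within-table pairs when ``traits_b`` is None), using
    pairwise-complete observations and average-rank ties.  Pairs pass when
    q < q_cutoff and |rho| > abs_rho_cutoff (defaults: FDR 0.01 and 0.35).
    Constant traits are excluded with a warning.
    """
    within = traits_b is None
    tb = traits_a if within else traits_b
    rows = []
    for i, ca in enumerate(traits_a.columns):
        cols_b = traits_a.columns[i + 1:] if within else tb.columns
        for cb in cols_b:
            x = traits_a[ca]
            y = tb[cb]
            mask = x.notna() & y.notna()
            if int(mask.sum()) < min_pairs:
                continue
            xv, yv = x[mask], y[mask]
            if xv.nunique() < 2 or yv.nunique() < 2:
                warnings.warn(f"constant trait in pair ({ca}, {cb}); excluded from screen")
                continue
            rho, p = stats.spearmanr(xv, yv)
            rows.append((ca, cb, float(rho), float(p)))
    if not rows:
        table = pd.DataFrame(columns=["trait_a", "trait_b", "rho", "p", "q", "pass"])
        return CorrelationScreen(table, q_cutoff, abs_rho_cutoff)
    table = pd.DataFrame(rows, columns=["trait_a", "trait_b", "rho", "p"])
    table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["pass"] = (table["q"] < q_cutoff) & (table["rho"].abs() > abs_rho_cutoff)
    return CorrelationScreen(table, q_cutoff, abs_rho_cutoff)


def comap_table(pairs: list[CoMapPair]) -> pd.DataFrame:
    """Flatten co-mapping pairs to the standard columns."""
    rows = [
        {
            "trait_a": p.peak_a.trait,
            "trait_b": p.peak_b.trait,
            "chr": p.peak_a.chromosome,
            "overlap_lo": p.overlap_lo,
            "overlap_hi": p.overlap_hi,
            "lod_a": p.peak_a.lod,
            "lod_b": p.peak_b.lod,
            "r_effects": p.r_effects if p.r_effects is not None else np.nan,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=["trait_a", "trait_b", "chr", "overlap_lo", "overlap_hi", "lod_a", "lod_b", "r_effects"])
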
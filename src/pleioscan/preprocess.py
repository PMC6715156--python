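"""Trait preparation: prevalence filtering, taxonomic agglomeration, CSS
normalization, rank-inverse-normal and log2 transforms, and internal-standard
normalization of LC-MS peak areas.

Count tables are pandas DataFrames with individuals on the rows and features
on the columns; taxonomy is a Series of Greengenes-style lineage strings
("k__...;p__...;...;g__...") indexed by feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

RANK_PREFIXES = ["k__", "p__", "c__", "o__", "f__", "g__", "s__"]
RANK_DEPTH = {"kingdom": 1, "phylum": 2, "class": 3, "order": 4, "family": 5, "genus": 6}

VALID_TRANSITIONS = {
    ("raw", "css"),
    ("css", "rint"),
    ("raw", "eq1"),
    ("eq1", "log2"),
}


@dataclass
class TraitTable:
    """Individuals x traits with per-trait class and transform-state tags.

    Transform states advance only along raw -> css -> rint (microbial) or
    raw -> eq1 -> log2 (metabolite); clinical traits stay raw or rint.
    """

    values: pd.DataFrame
    trait_class: dict[str, str] = field(default_factory=dict)
    transform: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in self.values.columns:
            self.trait_class.setdefault(t, "clinical")
            self.transform.setdefault(t, "raw")

    def set_transform(self, trait: str, new_state: str) -> None:
        """Advance a trait's transform state along the allowed chains
        (raw -> css -> rint for microbial, raw -> eq1 -> log2 for
        metabolite); anything else is a pipeline-order error."""
        old = self.transform.get(trait, "raw")
        if (old, new_state) not in VALID_TRANSITIONS:
            raise ValueError(f"invalid transform transition {old!r} -> {new_state!r} for {trait!r}")
        self.transform[trait] = new_state

    def subset(self, trait_class: str) -> pd.DataFrame:
        cols = [t for t in self.values.columns if self.trait_class[t] == trait_class]
        return self.values[cols]

    @staticmethod
    def concat(tables: list["TraitTable"]) -> "TraitTable":
        values = pd.concat([t.values for t in tables], axis=1)
        cls: dict[str, str] = {}
        tf: dict[str, str] = {}
        for t in tables:
            cls.update(t.trait_class)
            tf.update(t.transform)
        return TraitTable(values, cls, tf)


def cmm_filter(counts: pd.DataFrame, min_prevalence: float = 0.2) -> pd.DataFrame:
    """Core measurable microbiota filter: keep features with a nonzero count
    in at least ``min_prevalence`` of individuals (inclusive boundary).

    The 0.2 default matches the usual core-microbiota convention of taxa
    present in at least 20% of individuals.  Idempotent; column order kept.
    """
    if not (0.0 < min_prevalence <= 1.0):
        raise ValueError("min_prevalence must lie in (0, 1]")
    if counts.size == 0:
        raise ValueError("empty count table")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    prevalence = (counts > 0).mean(axis=0)
    return counts.loc[:, prevalence >= min_prevalence - 1e-12]


def _lineage_prefix(lineage: str, depth: int, feature: str) -> str:
    parts = [p.strip() for p in lineage.split(";")]
    if len(parts) > 7:
        raise ValueError(f"malformed lineage for feature {feature!r}: more than 7 ranks")
    for i, part in enumerate(parts):
        if part and not part[:3] == RANK_PREFIXES[i]:
            raise ValueError(f"malformed lineage for feature {feature!r}: {part!r} at rank {i}")
    assigned = [p for p in parts if len(p) > 3]
    if len(assigned) >= depth and len(parts) >= depth and len(parts[depth - 1]) > 3:
        return ";".join(parts[:depth])
    parent = assigned[-1] if assigned else "k__"
    return f"unclassified-{parent}"


def agglomerate(counts: pd.DataFrame, taxonomy: pd.Series, rank: str) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse features sharing a lineage prefix through ``rank`` by summing
    their counts; features unassigned at that rank fall into an explicit
    ``unclassified-<deepest assigned parent>`` bucket.

    Returns the collapsed table and a Series mapping each original feature to
    its group.  Column sums (per-sample totals) are conserved.
    """
    if rank not in RANK_DEPTH or rank == "kingdom":
        raise ValueError(f"rank must be one of {sorted(set(RANK_DEPTH) - {'kingdom'})}")
    depth = RANK_DEPTH[rank]
    missing = [f for f in counts.columns if f not in taxonomy.index]
    if missing:
        raise ValueError(f"no taxonomy for features {missing[:5]}")
    groups = pd.Series(
        {f: _lineage_prefix(taxonomy[f], depth, f) for f in counts.columns}, name="group"
    )
    collapsed = counts.T.groupby(groups, sort=False).sum().T
    return collapsed, groups


def css_normalize(
    counts: pd.DataFrame, quantile_l: float = 0.5, scale_constant: float = 1000.0
) -> pd.DataFrame:
    """Cumulative sum scaling.

    Per sample j, the scaling factor s_j is the sum of that sample's counts
    that are <= the ``quantile_l`` quantile of its *positive* counts; output
    is count / s_j * scale_constant.  Invariant to uniform per-sample scaling
    of the raw counts.
    """
    if not (0.0 < quantile_l < 1.0):
        raise ValueError("quantile_l must lie in (0, 1)")
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    out = np.empty_like(x)
    for j in range(x.shape[0]):
        row = x[j]
        pos = row[row > 0]
        if pos.size == 0:
            raise ValueError(f"sample {counts.index[j]!r} has all-zero counts")
        q = np.quantile(pos, quantile_l)
        s = row[row <= q].sum()
        out[j] = row / s * scale_constant
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def rank_inverse_normal(values, offset_c: float = 3.0 / 8.0):
    """Rank-based inverse normal transform (Blom offset by default).

    z_i = Phi^-1((r_i - c) / (n - 2c + 1)) with average ranks for ties;
    missing values stay missing.  Monotone in the input.
    """
    arr = np.asarray(values, dtype=float)
    mask = np.isfinite(arr)
    x = arr[mask]
    if x.size < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.ptp(x) == 0:
        raise ValueError("rank transform undefined for a constant vector")
    r = stats.rankdata(x, method="average")
    z = stats.norm.ppf((r - offset_c) / (x.size - 2 * offset_c + 1))
    out = np.full_like(arr, np.nan)
    out[mask] = z
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def rint_table(values: pd.DataFrame, offset_c: float = 3.0 / 8.0) -> pd.DataFrame:
    """Column-wise rank-inverse-normal transform of a trait table."""
    return values.apply(lambda col: rank_inverse_normal(col, offset_c))


def internal_standard_normalize(
    metabolites: pd.DataFrame, is_column: str = "IS_d4CDCA"
) -> pd.DataFrame:
    """Normalize peak areas to the internal-standard channel:
    out_ij = (area_ij / IS_j) * mean_j(IS_j).

    Removes per-sample injection/extraction factors while keeping the output
    on the original area scale; zeros are preserved.  The IS column is
    consumed and dropped from the output.
    """
    if is_column not in metabolites.columns:
        raise ValueError(f"internal-standard column {is_column!r} not found")
    is_area = metabolites[is_column].to_numpy(dtype=float)
    bad = np.flatnonzero(~(is_area > 0))
    if bad.size:
        raise ValueError(
            f"non-positive internal-standard area for sample {metabolites.index[bad[0]]!r}"
        )
    areas = metabolites.drop(columns=[is_column])
    if (areas.to_numpy() < 0).any():
        raise ValueError("peak areas must be non-negative")
    return areas.div(is_area, axis=0) * is_area.mean()


def log2_metabolites(metabolites: pd.DataFrame, pseudo: float = 0.0) -> pd.DataFrame:
    """log2(area + pseudo).  Areas must be non-negative, and strictly
    positive after adding the pseudo-count (areas are strictly positive after
    internal-standard normalization, so the default pseudo is 0)."""
    x = metabolites.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative peak area")
    if np.nanmin(x + pseudo) <= 0:
        raise ValueError("zero area with pseudo-count 0; pass pseudo > 0")
    return np.log2(metabolites + pseudo)


def prepare_microbial(
    counts: pd.DataFrame,
    taxonomy: pd.Series | None = None,
    min_prevalence: float = 0.2,
    agglomerate_ranks: list[str] | None = None,
    quantile_l: float = 0.5,
    scale_constant: float = 1000.0,
) -> TraitTable:
    """Full microbial pipeline: prevalence filter -> (optional agglomerated
    taxa appended) -> CSS -> rank-inverse-normal.  Returns a mapping-ready
    TraitTable tagged microbial/rint."""
    kept = cmm_filter(counts, min_prevalence)
    css = css_normalize(kept, quantile_l, scale_constant)
    tables = [css]
    if taxonomy is not None and agglomerate_ranks:
        for rank in agglomerate_ranks:
            agg, _ = agglomerate(css, taxonomy, rank)
            agg.columns = [f"{rank}:{c}" for c in agg.columns]
            tables.append(agg)
    merged = pd.concat(tables, axis=1)
    rint = rint_table(merged)
    return TraitTable(
        rint,
        {t: "microbial" for t in rint.columns},
        {t: "rint" for t in rint.columns},
    )


def prepare_metabolites(
    metabolites: pd.DataFrame,
    is_column: str = "IS_d4CDCA",
    pseudo: float = 0.0,
) -> TraitTable:
    """Metabolite pipeline: internal-standard normalization -> log2."""
    normed = internal_standard_normalize(metabolites, is_column)
    logged = log2_metabolites(normed, pseudo)
    return TraitTable(
        logged,
        {t: "metabolite" for t in logged.columns},
        {t: "log2" for t in logged.columns},
    )
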
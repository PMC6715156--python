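"""Mediation analysis by LOD drop and causal model selection.

A candidate mediator M of a target trait T at locus Q is evaluated by
rescanning T with M appended as an additive covariate: a drop of the LOD at
Q by more than 2 (the conventional screening criterion) implicates M on the
causal path.  Directionality is then classified by scoring four generative
models with BIC, each a product of Gaussian regressions given the locus
dosage Q and covariates C:

    M1 causal       f(M | Q, C) * f(T | M, C)
    M2 reactive     f(T | Q, C) * f(M | T, C)
    M3 independent  f(M | Q, C) * f(T | Q, C)
    M4 full         f(M | Q, C) * f(T | Q, M, C)

The verdict is the best-scoring model's label, or "undecided" when the
top-two BIC gap is inside the margin band or when the full model wins (no
direction resolved).  This is a penalized-likelihood variant of the causal
model selection test used in QTL mediation studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pleioscan.scan import (
    SUM_ZERO_BASIS,
    FounderDosage,
    GeneticMap,
    KinshipSet,
    covariate_design,
    genome_scan,
)


@dataclass
class MediationResult:
    """LOD at the locus before and after conditioning on the mediator."""

    target: str
    mediator: str
    chromosome: str
    marker: str
    lod_original: float
    lod_conditioned: float
    n_used: int

    def __post_init__(self) -> None:
        if self.lod_conditioned < 0 or self.lod_original < 0:
            raise ValueError("LOD values must be non-negative")

    @property
    def lod_drop(self) -> float:
        return self.lod_original - self.lod_conditioned

    @property
    def passes_drop_threshold(self) -> bool:
        return self.lod_drop > 2.0

    @property
    def negative_drop(self) -> bool:
        """Conditioned LOD exceeded the original (reported, never clipped)."""
        return self.lod_drop < 0


def mediation_scan(
    target,
    mediator,
    dosage: FounderDosage,
    gmap: GeneticMap,
    covariates: pd.DataFrame | None,
    kinship_set: KinshipSet | None,
    locus: str,
    target_name: str = "target",
    mediator_name: str = "mediator",
) -> MediationResult:
    """Rescan the target with the mediator as an additive covariate and
    report the LOD at ``locus`` before and after.

    Only individuals with values for both traits enter either scan, so the
    drop reflects conditioning rather than a sample change.  A mediator that
    is collinear with the existing covariates is rejected.
    """
    t = _as_array(target, dosage)
    m = _as_array(mediator, dosage)
    mask = np.isfinite(t) & np.isfinite(m)
    if int(mask.sum()) < 10:
        raise ValueError("too few individuals with both trait values")
    tv = np.where(mask, t, np.nan)
    chrom = str(gmap.markers.loc[locus, "chromosome"])
    X, _ = covariate_design(covariates, dosage.n_individuals)
    aug = np.column_stack([X[mask], m[mask]])
    if np.linalg.matrix_rank(aug) < aug.shape[1]:
        raise ValueError("mediator is collinear with existing covariates")
    scan0 = genome_scan(tv, dosage, gmap, covariates, kinship_set, trait_name=target_name)
    med_col = np.where(mask, m, 0.0)  # masked rows are dropped with the target
    scan1 = genome_scan(
        tv, dosage, gmap, covariates, kinship_set,
        trait_name=target_name, extra_covariates=med_col,
    )
    return MediationResult(
        target=target_name,
        mediator=mediator_name,
        chromosome=chrom,
        marker=locus,
        lod_original=float(scan0.lod.loc[locus]),
        lod_conditioned=float(scan1.lod.loc[locus]),
        n_used=int(mask.sum()),
    )


def _as_array(y, dosage: FounderDosage) -> np.ndarray:
    if isinstance(y, pd.Series):
        return y.reindex(dosage.individuals).to_numpy(dtype=float)
    arr = np.asarray(y, dtype=float)
    if arr.shape[0] != dosage.n_individuals:
        raise ValueError("trait length does not match dosage individuals")
    return arr


# ---------------------------------------------------------------------------
# Causal model selection
# ---------------------------------------------------------------------------

MODEL_LABELS = {"m1": "causal", "m2": "reactive", "m3": "independent", "m4": "undecided"}


def _gauss_bic(y: np.ndarray, X: np.ndarray) -> float:
    """BIC of a Gaussian linear regression (k = coefficients + variance)."""
    n = y.size
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if rss <= 0:
        raise ValueError("zero residual variance in model-selection regression")
    k = X.shape[1] + 1
    return n * np.log(rss / n) + k * np.log(n)


@dataclass
class CausalVerdict:
    """BIC scores of the four causal models and the selected label."""

    scores: dict[str, float]
    label: str
    margin: float
    margin_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.label not in ("causal", "reactive", "independent", "undecided"):
            raise ValueError(f"unknown verdict label {self.label!r}")


def causal_model_selection(
    target,
    mediator,
    dosage_at_locus: np.ndarray,
    covariates: pd.DataFrame | None = None,
    margin_threshold: float = 2.0,
) -> CausalVerdict:
    """Classify the target-mediator relationship at a locus.

    The locus enters as the 8-column founder dosage (allele scan).  The four
    models are scored by summed BIC of their two Gaussian factors; the label
    is "undecided" whenever the top-two gap is below ``margin_threshold`` or
    the full model M4 scores best.
    """
    t = np.asarray(target, dtype=float).ravel()
    m = np.asarray(mediator, dtype=float).ravel()
    D = np.asarray(dosage_at_locus, dtype=float)
    mask = np.isfinite(t) & np.isfinite(m)
    n = int(mask.sum())
    if n < 30:
        raise ValueError("need at least 30 complete cases for causal model selection")
    t, m, D = t[mask], m[mask], D[mask]
    if np.ptp(t) == 0 or np.ptp(m) == 0:
        raise ValueError("zero-variance trait")
    C, _ = covariate_design(covariates, len(mask))
    C = C[mask] if C.shape[0] == mask.size else C
    G = D @ SUM_ZERO_BASIS
    CQ = np.column_stack([C, G])
    scores = {
        "m1": _gauss_bic(m, CQ) + _gauss_bic(t, np.column_stack([C, m])),
        "m2": _gauss_bic(t, CQ) + _gauss_bic(m, np.column_stack([C, t])),
        "m3": _gauss_bic(m, CQ) + _gauss_bic(t, CQ),
        "m4": _gauss_bic(m, CQ) + _gauss_bic(t, np.column_stack([CQ, m])),
    }
    order = sorted(scores, key=scores.get)
    margin = scores[order[1]] - scores[order[0]]
    if order[0] == "m4" or margin < margin_threshold:
        label = "undecided"
    else:
        label = MODEL_LABELS[order[0]]
    return CausalVerdict(scores=scores, label=label, margin=float(margin), margin_threshold=margin_threshold)


@dataclass
class BidirectionalReport:
    """Mediation run in both directions plus one causal verdict.

    Drops > 2 in both directions are evidence consistent with bidirectional
    coupling (partial mediation in both models)."""

    a_given_b: MediationResult  # trait A conditioned on B
    b_given_a: MediationResult
    verdict: CausalVerdict

    @property
    def bidirectional(self) -> bool:
        return self.a_given_b.passes_drop_threshold and self.b_given_a.passes_drop_threshold


def bidirectional_report(
    trait_a,
    trait_b,
    dosage: FounderDosage,
    gmap: GeneticMap,
    covariates: pd.DataFrame | None,
    kinship_set: KinshipSet | None,
    locus: str,
    name_a: str = "trait_a",
    name_b: str = "trait_b",
) -> BidirectionalReport:
    """Run the mediation scan in both directions and classify causality once."""
    a = _as_array(trait_a, dosage)
    b = _as_array(trait_b, dosage)
    if name_a == name_b or np.array_equal(
        np.nan_to_num(a, nan=np.inf), np.nan_to_num(b, nan=np.inf)
    ):
        raise ValueError("self-pair: the two traits are identical")
    res_ab = mediation_scan(a, b, dosage, gmap, covariates, kinship_set, locus, name_a, name_b)
    res_ba = mediation_scan(b, a, dosage, gmap, covariates, kinship_set, locus, name_b, name_a)
    mi = gmap.marker_index(locus)
    verdict = causal_model_selection(b, a, dosage.dosage[:, mi, :], covariates)
    return BidirectionalReport(a_given_b=res_ab, b_given_a=res_ba, verdict=verdict)
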
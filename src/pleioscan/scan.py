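"""Haplotype-regression genome scans with LOCO kinship.

The mapping model regresses a phenotype on the 8 founder-haplotype dosages at
each marker, with additive covariates and a polygenic random effect whose
covariance is a kinship matrix computed from all chromosomes except the one
being scanned (leave one chromosome out, LOCO).  The variance ratio
h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) is estimated once per (trait,
chromosome) under the no-QTL null by REML and held fixed across markers; each
marker is then fit by generalized least squares in the eigenbasis of K.  The
mapping statistic is LOD = (n/2) log10(RSS0 / RSS1).

Founder coefficients use a sum-to-zero contrast so all eight strains are
treated symmetrically (the eight dosages sum to 2 and are collinear with the
intercept, so only seven contrasts are identifiable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.optimize import minimize_scalar

from pleioscan.simulate import FounderDosage, GeneticMap

#: 8 x 7 orthonormal basis of the sum-to-zero subspace of founder effects.
SUM_ZERO_BASIS = helmert(8).T


def covariate_design(covariates: pd.DataFrame | None, n: int | None = None) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix: intercept, sex, wave dummies (first level
    as reference), and centered/scaled days on diet.  Extra numeric columns
    are passed through centered."""
    if covariates is None:
        if n is None:
            raise ValueError("need n when covariates is None")
        return np.ones((n, 1)), ["intercept"]
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    for c in covariates.columns:
        v = covariates[c]
        if c == "wave":
            levels = sorted(v.unique())
            for lev in levels[1:]:
                cols.append((v == lev).to_numpy(dtype=float))
                names.append(f"wave_{lev}")
        else:
            x = v.to_numpy(dtype=float)
            s = x.std()
            cols.append((x - x.mean()) / (s if s > 0 else 1.0))
            names.append(str(c))
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipSet:
    """One kinship matrix per left-out chromosome, with cached
    eigendecompositions.  K_ij = (1/M') sum over markers not on the left-out
    chromosome of sum_f (d_imf/2)(d_jmf/2)."""

    matrices: dict[str, np.ndarray]
    individuals: list[str]
    method: str = "loco"
    _eigen: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for chrom, K in self.matrices.items():
            if np.abs(K - K.T).max() > 1e-10:
                raise ValueError(f"kinship for chromosome {chrom} not symmetric")

    def eigen(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition with eigenvalues normalized to mean 1, so the
        variance ratio h2 reads as a fraction of trait variance."""
        if chrom not in self._eigen:
            w, U = np.linalg.eigh(self.matrices[chrom])
            if w.min() < -1e-8:
                raise ValueError(f"kinship for chromosome {chrom} not positive semidefinite")
            self._eigen[chrom] = (_normalize_eigs(w), U)
        return self._eigen[chrom]


def compute_kinship_overall(dosage: FounderDosage) -> np.ndarray:
    """Genome-wide kinship from all markers (used for polygenic simulation
    and non-LOCO fits)."""
    n, m, _ = dosage.dosage.shape
    P = (dosage.dosage / 2.0).reshape(n, m * 8)
    return (P @ P.T) / m


def compute_kinship_loco(dosage: FounderDosage, gmap: GeneticMap) -> KinshipSet:
    """LOCO kinship: for each chromosome, average founder-probability
    cross-products over the markers on all *other* chromosomes."""
    chroms = gmap.chromosomes
    if len(chroms) < 2:
        raise ValueError("LOCO kinship needs >= 2 chromosomes; use compute_kinship_overall")
    n, m, _ = dosage.dosage.shape
    P = dosage.dosage / 2.0
    total = np.einsum("imf,jmf->ij", P, P, optimize=True)
    matrices = {}
    for chrom in chroms:
        idx = gmap.chrom_slice(chrom)
        Pc = P[:, idx, :]
        Sc = np.einsum("imf,jmf->ij", Pc, Pc, optimize=True)
        matrices[chrom] = (total - Sc) / (m - len(idx))
    return KinshipSet(matrices, list(dosage.individuals))


# ---------------------------------------------------------------------------
# Null mixed model
# ---------------------------------------------------------------------------


def _normalize_eigs(w: np.ndarray) -> np.ndarray:
    """Clip tiny negatives and rescale eigenvalues to mean 1 (equivalent to
    dividing K by its average diagonal), making h2 a variance fraction."""
    w = np.clip(w, 0.0, None)
    mean = w.mean()
    return w / mean if mean > 0 else w


def _reml_loglik(h2: float, yr: np.ndarray, Xr: np.ndarray, w: np.ndarray) -> float:
    n, p = Xr.shape
    v = h2 * w + (1.0 - h2)
    vi = 1.0 / v
    XtVi = Xr.T * vi
    XtViX = XtVi @ Xr
    beta = np.linalg.solve(XtViX, XtVi @ yr)
    resid = yr - Xr @ beta
    rss = float(resid @ (vi * resid))
    if rss <= 0:
        raise ValueError("zero residual variance after covariates")
    sigma2 = rss / (n - p)
    sign, logdet = np.linalg.slogdet(XtViX)
    return -0.5 * ((n - p) * np.log(sigma2) + np.log(v).sum() + logdet + (n - p))


def fit_null_lmm(
    y: np.ndarray,
    covariates: np.ndarray,
    K: np.ndarray | None = None,
    eigen: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float]:
    """REML estimate of h2 = sigma_g^2/(sigma_g^2+sigma_e^2) for
    y = X beta + u + e with u ~ N(0, sigma_g^2 K), e ~ N(0, sigma_e^2 I).

    Returns (h2, restricted log-likelihood).  When the likelihood is flat in
    h2 (e.g. K = I), the boundary convention h2 = 0 is used.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite (drop missing values first)")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    if eigen is None:
        if K is None:
            raise ValueError("need K or its eigendecomposition")
        w, U = np.linalg.eigh(K)
        if w.min() < -1e-8:
            raise ValueError("K is not positive semidefinite")
    else:
        w, U = eigen
    w = _normalize_eigs(w)
    yr = U.T @ y
    Xr = U.T @ X

    def neg(h2: float) -> float:
        return -_reml_loglik(h2, yr, Xr, w)

    ll0 = -neg(0.0)
    res = minimize_scalar(neg, bounds=(0.0, 0.999), method="bounded", options={"xatol": 1e-6})
    if -res.fun > ll0 + 1e-8:
        return float(res.x), float(-res.fun)
    return 0.0, float(ll0)


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """LOD curve over all markers for one trait, with the per-chromosome
    null variance ratios used in the GLS weights."""

    trait: str
    lod: pd.Series  # indexed by marker id
    h2_by_chrom: dict[str, float]
    n_used: int
    covariate_names: list[str]

    def __post_init__(self) -> None:
        vals = self.lod.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("LOD curve contains non-finite values")

    def chrom_curve(self, gmap: GeneticMap, chrom: str) -> pd.Series:
        return self.lod.iloc[gmap.chrom_slice(chrom)]


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y on X (via thin QR)."""
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ Y
    return np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", proj, proj)


def _align_trait(y, dosage: FounderDosage) -> tuple[np.ndarray, np.ndarray]:
    """Return (values over all individuals, boolean complete-case mask)."""
    if isinstance(y, pd.Series):
        if not y.index.equals(pd.Index(dosage.individuals)):
            try:
                y = y.reindex(dosage.individuals)
            except Exception as exc:  # pragma: no cover
                raise ValueError("trait ids do not align with dosage individuals") from exc
        arr = y.to_numpy(dtype=float)
    else:
        arr = np.asarray(y, dtype=float)
        if arr.shape[0] != dosage.n_individuals:
            raise ValueError("trait length does not match dosage individuals")
    mask = np.isfinite(arr)
    if not mask.any():
        raise ValueError("all trait values missing")
    return arr, mask


def genome_scan(
    y,
    dosage: FounderDosage,
    gmap: GeneticMap,
    covariates: pd.DataFrame | None = None,
    kinship_set: KinshipSet | None = None,
    trait_name: str = "trait",
    extra_covariates: np.ndarray | None = None,
) -> ScanResult:
    """LOD genome scan of one trait on founder haplotype dosages.

    Missing trait values are dropped trait-wise (complete cases).  With a
    kinship set, markers on chromosome c are tested under the LOCO kinship
    for c with GLS weights from that chromosome's null h2; without one, the
    scan is an ordinary regression.  ``extra_covariates`` (e.g. a mediator)
    are appended to the design of both null and alternative models.
    """
    arr, mask = _align_trait(y, dosage)
    yv = arr[mask]
    n = int(mask.sum())
    X_full, names = covariate_design(covariates, dosage.n_individuals)
    X = X_full[mask]
    if extra_covariates is not None:
        extra = np.atleast_2d(np.asarray(extra_covariates, dtype=float))
        if extra.shape[0] != dosage.n_individuals:
            extra = extra.T
        X = np.column_stack([X, extra[mask]])
        names = names + [f"extra_{i}" for i in range(extra.shape[1])]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix (including extra covariates) is rank deficient")

    # degenerate trait: no residual variance -> flat zero LOD by convention
    base_rss = float(_rss(X, yv[:, None])[0])
    lod = np.zeros(gmap.n_markers)
    h2_by_chrom: dict[str, float] = {}
    if base_rss <= 1e-12 * max(1.0, float(yv @ yv)):
        return ScanResult(trait_name, pd.Series(lod, index=gmap.markers.index), {c: 0.0 for c in gmap.chromosomes}, n, names)

    D = dosage.dosage[mask] @ SUM_ZERO_BASIS  # n x M x 7
    for chrom in gmap.chromosomes:
        idx = gmap.chrom_slice(chrom)
        if kinship_set is not None:
            if mask.all():
                w, U = kinship_set.eigen(chrom)
            else:
                Ksub = kinship_set.matrices[chrom][np.ix_(mask, mask)]
                w, U = np.linalg.eigh(Ksub)
                w = _normalize_eigs(w)
            h2, _ = fit_null_lmm(yv, X, eigen=(w, U))
            wts = 1.0 / np.sqrt(h2 * w + (1.0 - h2))
            yt = wts * (U.T @ yv)
            Xt = wts[:, None] * (U.T @ X)
            Gt = wts[:, None, None] * np.tensordot(U.T, D[:, idx, :], axes=(1, 0))
        else:
            h2 = 0.0
            yt, Xt, Gt = yv, X, D[:, idx, :]
        h2_by_chrom[chrom] = h2
        rss0 = float(_rss(Xt, yt[:, None])[0])
        Y1 = yt[:, None]
        for k, mi in enumerate(idx):
            rss1 = float(_rss(np.column_stack([Xt, Gt[:, k, :]]), Y1)[0])
            rss1 = min(rss1, rss0)  # guard fp noise; models are nested
            lod[mi] = (n / 2.0) * np.log10(rss0 / max(rss1, 1e-300))
    return ScanResult(trait_name, pd.Series(lod, index=gmap.markers.index), h2_by_chrom, n, names)


def _ols_scan_matrix(Y: np.ndarray, X: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Batched ordinary-regression scan: LOD (markers x traits) for traits Y
    (n x T), covariates X (n x p), dosage contrasts G (n x M x 7)."""
    n, T = Y.shape
    rss0 = _rss(X, Y)
    M = G.shape[1]
    lod = np.empty((M, T))
    for m in range(M):
        rss1 = np.minimum(_rss(np.column_stack([X, G[:, m, :]]), Y), rss0)
        lod[m] = (n / 2.0) * np.log10(rss0 / np.maximum(rss1, 1e-300))
    return lod


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------


@dataclass
class ThresholdSet:
    """Genome-wide LOD thresholds by alpha, from the pooled permutation
    distribution of genome-wide maximum LOD scores."""

    thresholds: dict[float, float]
    n_perm: int
    pooled: bool
    max_lods: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self) -> None:
        alphas = sorted(self.thresholds)
        vals = [self.thresholds[a] for a in alphas]
        if any(vals[i] < vals[i + 1] - 1e-9 for i in range(len(vals) - 1)):
            raise ValueError("thresholds must decrease as alpha increases")

    def __getitem__(self, alpha: float) -> float:
        return self.thresholds[alpha]


def permutation_thresholds(
    traits: pd.DataFrame,
    dosage: FounderDosage,
    gmap: GeneticMap,
    covariates: pd.DataFrame | None = None,
    kinship_set: KinshipSet | None = None,
    n_perm: int = 1000,
    alphas: tuple[float, ...] = (0.05, 0.2, 0.5),
    pooled: bool = True,
    seed: int | None = None,
) -> ThresholdSet:
    """Permutation-based genome-wide LOD thresholds.

    Each permutation shuffles the rows of (phenotype + covariates) jointly
    against the genotypes, preserving trait-covariate association, and
    records the genome-wide maximum LOD.  With ``pooled`` the max-LOD values
    of all traits enter one distribution and a single threshold per alpha is
    returned (its (1-alpha) quantile); this mirrors using a common threshold
    across phenotypes.  One shared permutation order per iteration is applied
    to every trait, so an iteration contributes one max-LOD per trait.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10 (>= 100 recommended)")
    if any(not (0.0 < a < 1.0) for a in alphas):
        raise ValueError("alphas must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = dosage.n_individuals
    max_lods = np.empty((n_perm, traits.shape[1]))
    if kinship_set is None and not traits.isna().any().any():
        Y = traits.to_numpy(dtype=float)
        X, _ = covariate_design(covariates, n)
        G = dosage.dosage @ SUM_ZERO_BASIS
        for b in range(n_perm):
            perm = rng.permutation(n)
            lod = _ols_scan_matrix(Y[perm], X[perm], G)
            max_lods[b] = lod.max(axis=0)
    else:
        for b in range(n_perm):
            perm = rng.permutation(n)
            cov_p = covariates.iloc[perm].reset_index(drop=True) if covariates is not None else None
            if cov_p is not None:
                cov_p.index = pd.Index(dosage.individuals, name="individual")
            for t, name in enumerate(traits.columns):
                yp = pd.Series(traits[name].to_numpy()[perm], index=dosage.individuals)
                res = genome_scan(yp, dosage, gmap, cov_p, kinship_set, trait_name=name)
                max_lods[b, t] = res.lod.max()
    pool = max_lods.ravel() if pooled else max_lods
    thresholds = {float(a): float(np.quantile(pool, 1.0 - a)) for a in alphas}
    return ThresholdSet(thresholds, n_perm, pooled, max_lods)


# ---------------------------------------------------------------------------
# Support intervals and peaks
# ---------------------------------------------------------------------------


def bayes_interval(
    lod_curve: np.ndarray,
    positions: np.ndarray | None = None,
    prob: float = 0.95,
    peak_index: int | None = None,
) -> tuple[int, int] | tuple[float, float]:
    """Approximate Bayes support interval on one chromosome.

    The posterior over the marker grid is proportional to 10^LOD; the
    interval is grown symmetrically outward from the peak marker (the curve
    maximum, or ``peak_index`` when given — used for secondary peaks on a
    multi-peak chromosome) until its mass reaches ``prob``.  Returns marker
    indices, or positions when ``positions`` is given.
    """
    lod = np.asarray(lod_curve, dtype=float)
    if lod.size < 2:
        raise ValueError("need at least 2 markers")
    if not np.all(np.isfinite(lod)):
        raise ValueError("non-finite LOD values")
    post = np.power(10.0, lod - lod.max())
    post /= post.sum()
    peak = int(np.argmax(lod)) if peak_index is None else int(peak_index)
    lo = hi = peak
    mass = post[peak]
    while mass < prob and (lo > 0 or hi < lod.size - 1):
        if lo > 0:
            lo -= 1
            mass += post[lo]
        if hi < lod.size - 1:
            hi += 1
            mass += post[hi]
    if positions is not None:
        return float(positions[lo]), float(positions[hi])
    return lo, hi


@dataclass
class QtlPeak:
    """One called QTL: position, LOD, 95% Bayes support interval, and the
    eight sum-to-zero founder coefficients (A..H order)."""

    trait: str
    chromosome: str
    marker: str
    pos_Mbp: float
    pos_cM: float
    lod: float
    ci_lo: float
    ci_hi: float
    coefs: np.ndarray | None = None
    trait_class: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_lo - 1e-9 <= self.pos_Mbp <= self.ci_hi + 1e-9):
            raise ValueError("peak position must lie inside its support interval")


def find_peaks(
    scan: ScanResult,
    gmap: GeneticMap,
    threshold: float,
    min_peak_separation_cM: float = 10.0,
    interval_prob: float = 0.95,
    trait_class: str = "",
) -> list[QtlPeak]:
    """Call peaks per chromosome: local maxima with LOD >= threshold, merging
    maxima closer than the separation window (keeping the higher), each with
    its Bayes support interval.  Use :func:`peaks_for_trait` to also attach
    founder coefficients."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peaks: list[QtlPeak] = []
    lod_all = scan.lod.to_numpy()
    for chrom in gmap.chromosomes:
        idx = gmap.chrom_slice(chrom)
        lod = lod_all[idx]
        cm = gmap.markers["pos_cM"].to_numpy()[idx]
        mbp = gmap.markers["pos_Mbp"].to_numpy()[idx]
        cand = [
            i
            for i in range(len(lod))
            if lod[i] >= threshold
            and (i == 0 or lod[i] >= lod[i - 1])
            and (i == len(lod) - 1 or lod[i] >= lod[i + 1])
        ]
        cand.sort(key=lambda i: -lod[i])
        kept: list[int] = []
        for i in cand:
            if all(abs(cm[i] - cm[j]) >= min_peak_separation_cM for j in kept):
                kept.append(i)
        for i in sorted(kept):
            # interval around THIS peak: restrict to the sub-curve between
            # flanking kept peaks so multi-peak chromosomes get local
            # intervals, expanding from the called peak itself
            left = max([j for j in kept if j < i], default=None)
            right = min([j for j in kept if j > i], default=None)
            a = 0 if left is None else (left + i) // 2 + 1
            b = len(lod) if right is None else (right + i) // 2 + 1
            if b - a >= 2:
                lo, hi = bayes_interval(lod[a:b], mbp[a:b], interval_prob, peak_index=i - a)
            else:
                lo, hi = bayes_interval(lod, mbp, interval_prob, peak_index=i)
            peaks.append(
                QtlPeak(
                    trait=scan.trait,
                    chromosome=chrom,
                    marker=str(gmap.markers.index[idx[i]]),
                    pos_Mbp=float(mbp[i]),
                    pos_cM=float(cm[i]),
                    lod=float(lod[i]),
                    ci_lo=lo,
                    ci_hi=hi,
                    trait_class=trait_class,
                )
            )
    return peaks


def peaks_for_trait(
    y,
    scan: ScanResult,
    gmap: GeneticMap,
    threshold: float,
    dosage: FounderDosage,
    covariates: pd.DataFrame | None = None,
    kinship_set: KinshipSet | None = None,
    min_peak_separation_cM: float = 10.0,
    trait_class: str = "",
) -> list[QtlPeak]:
    """find_peaks plus founder coefficients estimated at each peak marker."""
    peaks = find_peaks(
        scan, gmap, threshold, min_peak_separation_cM, trait_class=trait_class
    )
    arr, mask = _align_trait(y, dosage)
    for p in peaks:
        mi = gmap.marker_index(p.marker)
        K = kinship_set.matrices[p.chromosome] if kinship_set is not None else None
        p.coefs = founder_effects(
            arr, dosage.dosage[:, mi, :], covariates, K=K,
        )
    return peaks


def founder_effects(
    y,
    dosage_at_marker: np.ndarray,
    covariates: pd.DataFrame | None = None,
    K: np.ndarray | None = None,
    kinship_set: KinshipSet | None = None,
    chrom: str | None = None,
    shrink: float = 0.0,
) -> np.ndarray:
    """Sum-to-zero founder coefficients at one marker from a GLS fit.

    ``shrink`` adds a ridge penalty on the founder contrasts (display
    stability for poorly represented founders); coefficients of a constant
    trait are all zero.
    """
    arr = np.asarray(y, dtype=float) if not isinstance(y, pd.Series) else y.to_numpy(dtype=float)
    mask = np.isfinite(arr)
    yv = arr[mask]
    if yv.size < 9:
        raise ValueError("too few complete cases for founder effects")
    if np.ptp(yv) == 0:
        return np.zeros(8)
    Dm = np.asarray(dosage_at_marker, dtype=float)[mask]
    Xc, _ = covariate_design(covariates, arr.size)
    Xc = Xc[mask]
    if kinship_set is not None and chrom is not None:
        K = kinship_set.matrices[chrom]
    if K is not None:
        Ksub = K[np.ix_(mask, mask)]
        w, U = np.linalg.eigh(Ksub)
        w = _normalize_eigs(w)
        h2, _ = fit_null_lmm(yv, Xc, eigen=(w, U))
        wts = 1.0 / np.sqrt(h2 * w + (1.0 - h2))
        yv = wts * (U.T @ yv)
        Xc = wts[:, None] * (U.T @ Xc)
        Dm = wts[:, None] * (U.T @ Dm)
    G = Dm @ SUM_ZERO_BASIS
    Z = np.column_stack([Xc, G])
    p = Xc.shape[1]
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        warnings.warn("collinear dosage columns at marker; coefficients are a minimum-norm solution")
    if shrink > 0:
        A = Z.T @ Z
        A[p:, p:] += shrink * np.eye(7)
        beta = np.linalg.solve(A, Z.T @ yv)
    else:
        beta = np.linalg.lstsq(Z, yv, rcond=None)[0]
    return SUM_ZERO_BASIS @ beta[p:]
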
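"""Pleiotropy versus two-linked-loci likelihood-ratio test.

For two traits mapping to the same region, the null hypothesis is a single
shared locus (pleiotropy) and the alternative is two distinct loci.  For
every ordered pair of positions (lambda1, lambda2) in the interval the
bivariate model

    y1 = [C, G(lambda1)] b1 + e1,   y2 = [C, G(lambda2)] b2 + e2,

with shared covariates C, founder-dosage contrasts G and an unstructured
2x2 residual covariance, is fit by iterated feasible GLS (seemingly
unrelated regressions; on the diagonal lambda1 = lambda2 the fit is the
exact multivariate-regression MLE).  The test statistic is

    lrt = [max over all pairs - max over the diagonal] profile log-lik / ln 10,

i.e. the log10 likelihood ratio of the two-locus model over the pleiotropic
one.  Significance comes from a parametric bootstrap: data are resimulated
from the fitted pleiotropic null (bivariate normal residuals around the
fitted means at the diagonal argmax) and the statistic recomputed, with the
plus-one estimator p = (1 + #{lrt_b >= lrt_obs}) / (B + 1).

All positions in the interval are evaluated as an ordered grid; profile
log-likelihood values are reported in log10 units relative to the surface
maximum.  Kinship is omitted from the bivariate model by default; a shared
single-rotation kinship whitening is available via ``kinship=``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pleioscan.scan import SUM_ZERO_BASIS, covariate_design, fit_null_lmm

_LN10 = np.log(10.0)


class _SurGrid:
    """Precomputed cross-product tensors for profile fits over a marker grid.

    Everything that depends only on the design (covariates and dosage
    contrasts) is computed once, so bootstrap replicates pay only for the
    trait-side products.
    """

    def __init__(self, C: np.ndarray, G: np.ndarray, max_iter: int = 80, tol: float = 1e-9):
        self.n, self.M = G.shape[0], G.shape[1]
        self.pc = C.shape[1]
        self.p = self.pc + G.shape[2]
        self.C, self.G = C, G
        self.max_iter, self.tol = max_iter, tol
        CC = C.T @ C
        CG = np.einsum("np,nmk->mpk", C, G)  # (M, pc, 7)
        GG = np.einsum("nik,njl->ijkl", G, G)  # (M, M, 7, 7)
        p, pc, M = self.p, self.pc, self.M
        AA = np.empty((M, M, p, p))
        AA[:, :, :pc, :pc] = CC
        AA[:, :, :pc, pc:] = CG[None, :, :, :]
        AA[:, :, pc:, :pc] = CG.transpose(0, 2, 1)[:, None, :, :]
        AA[:, :, pc:, pc:] = GG
        I, J = np.meshgrid(np.arange(M), np.arange(M), indexing="ij")
        self.I, self.J = I.ravel(), J.ravel()
        self.Aii = AA[self.I, self.I]
        self.Aij = AA[self.I, self.J]
        self.Ajj = AA[self.J, self.J]

    def _zy(self, Y: np.ndarray) -> np.ndarray:
        """Z_m' y_k for every marker m and trait k: (M, p, 2)."""
        Cy = self.C.T @ Y  # (pc, 2)
        Gy = np.einsum("nmk,nt->mkt", self.G, Y)  # (M, 7, 2)
        Zy = np.empty((self.M, self.p, 2))
        Zy[:, : self.pc, :] = Cy[None]
        Zy[:, self.pc:, :] = Gy
        return Zy

    def profile(self, Y: np.ndarray) -> tuple[np.ndarray, dict]:
        """Profile log10-likelihood surface (M x M) for the trait pair Y
        (n x 2), maximized over coefficients and residual covariance."""
        n, p = self.n, self.p
        yy = Y.T @ Y
        Zy = self._zy(Y)
        I, J = self.I, self.J
        ncell = I.size
        # per-equation OLS start
        b1 = np.linalg.solve(self.Aii, Zy[I, :, 0][..., None])[..., 0]
        b2 = np.linalg.solve(self.Ajj, Zy[J, :, 1][..., None])[..., 0]
        S11 = yy[0, 0] - np.einsum("cp,cp->c", b1, Zy[I, :, 0])
        S22 = yy[1, 1] - np.einsum("cp,cp->c", b2, Zy[J, :, 1])
        S12 = (
            yy[0, 1]
            - np.einsum("cp,cp->c", b1, Zy[I, :, 1])
            - np.einsum("cp,cp->c", b2, Zy[J, :, 0])
            + np.einsum("cp,cpq,cq->c", b1, self.Aij, b2)
        )
        prev = np.full(ncell, np.inf)
        Mmat = np.empty((ncell, 2 * p, 2 * p))
        rhs = np.empty((ncell, 2 * p))
        converged = False
        for _ in range(self.max_iter):
            # GLS normal equations scaled by det(S): the solution is invariant
            # to that scaling, and avoiding the division keeps near-singular
            # residual covariances (perfectly correlated traits) finite
            W11, W22, W12 = S22, S11, -S12
            Mmat[:, :p, :p] = W11[:, None, None] * self.Aii
            Mmat[:, :p, p:] = W12[:, None, None] * self.Aij
            Mmat[:, p:, :p] = W12[:, None, None] * self.Aij.transpose(0, 2, 1)
            Mmat[:, p:, p:] = W22[:, None, None] * self.Ajj
            rhs[:, :p] = W11[:, None] * Zy[I, :, 0] + W12[:, None] * Zy[I, :, 1]
            rhs[:, p:] = W12[:, None] * Zy[J, :, 0] + W22[:, None] * Zy[J, :, 1]
            scale = np.einsum("cii->c", Mmat) / (2 * p)
            Mmat[:, np.arange(2 * p), np.arange(2 * p)] += 1e-10 * np.maximum(scale, 1e-300)[:, None]
            b = np.linalg.solve(Mmat, rhs[..., None])[..., 0]
            b1, b2 = b[:, :p], b[:, p:]
            S11 = (
                yy[0, 0]
                - 2 * np.einsum("cp,cp->c", b1, Zy[I, :, 0])
                + np.einsum("cp,cpq,cq->c", b1, self.Aii, b1)
            )
            S22 = (
                yy[1, 1]
                - 2 * np.einsum("cp,cp->c", b2, Zy[J, :, 1])
                + np.einsum("cp,cpq,cq->c", b2, self.Ajj, b2)
            )
            S12 = (
                yy[0, 1]
                - np.einsum("cp,cp->c", b1, Zy[I, :, 1])
                - np.einsum("cp,cp->c", b2, Zy[J, :, 0])
                + np.einsum("cp,cpq,cq->c", b1, self.Aij, b2)
            )
            cur = S11 * S22 - S12 * S12
            if np.max(np.abs(np.log(np.maximum(cur, 1e-300)) - np.log(np.maximum(prev, 1e-300)))) < self.tol:
                converged = True
                prev = cur
                break
            prev = cur
        det = np.maximum(S11 * S22 - S12 * S12, 1e-300)
        ll10 = (-(n / 2.0) * np.log(det / (n * n))) / _LN10
        surface = ll10.reshape(self.M, self.M)
        extras = {"b1": b1, "b2": b2, "S11": S11, "S22": S22, "S12": S12, "converged": converged}
        return surface, extras

    def lrt(self, Y: np.ndarray) -> tuple[float, np.ndarray, dict]:
        surface, extras = self.profile(Y)
        diag = np.diag(surface)
        stat = float(surface.max() - diag.max())
        return max(stat, 0.0), surface, extras


@dataclass
class PleiotropyResult:
    """Profile surface, test statistic and (optionally) bootstrap p."""

    surface: np.ndarray  # (M, M) log10 profile likelihood, max at 0
    lrt: float
    argmax: tuple[int, int]
    diag_argmax: int
    markers: list[str] = field(default_factory=list)
    B: int | None = None
    pvalue: float | None = None
    n_nonconverged: int = 0

    def __post_init__(self) -> None:
        if self.lrt < 0:
            raise ValueError("lrt must be non-negative")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValueError("bootstrap p must lie in (0, 1]")


def _prepare(y1, y2, dosage_interval, covariates, kinship):
    y1 = np.asarray(y1, dtype=float).ravel()
    y2 = np.asarray(y2, dtype=float).ravel()
    D = np.asarray(dosage_interval, dtype=float)
    if D.ndim != 3 or D.shape[2] != 8:
        raise ValueError("dosage_interval must be (individuals, markers, 8)")
    if D.shape[1] < 2:
        raise ValueError("interval must contain at least 2 markers")
    mask = np.isfinite(y1) & np.isfinite(y2)
    if int(mask.sum()) < 3:
        raise ValueError("fewer than 3 complete trait pairs")
    Y = np.column_stack([y1[mask], y2[mask]])
    if isinstance(covariates, pd.DataFrame):
        C, _ = covariate_design(covariates, len(y1))
    elif covariates is None:
        C = np.ones((len(y1), 1))
    else:
        C = np.asarray(covariates, dtype=float)
    C = C[mask]
    G = D[mask] @ SUM_ZERO_BASIS
    if kinship is not None:
        # shared-rotation whitening: one h2 (average of the two traits' null
        # REML estimates) applied to both equations
        from pleioscan.scan import _normalize_eigs

        Ksub = np.asarray(kinship)[np.ix_(mask, mask)]
        w, U = np.linalg.eigh(Ksub)
        w = _normalize_eigs(w)
        h2a, _ = fit_null_lmm(Y[:, 0], C, eigen=(w, U))
        h2b, _ = fit_null_lmm(Y[:, 1], C, eigen=(w, U))
        h2 = 0.5 * (h2a + h2b)
        wts = 1.0 / np.sqrt(h2 * w + (1.0 - h2))
        Y = wts[:, None] * (U.T @ Y)
        C = wts[:, None] * (U.T @ C)
        G = wts[:, None, None] * np.tensordot(U.T, G, axes=(1, 0))
    return Y, C, G, mask


def bivariate_profile(
    y1,
    y2,
    dosage_interval: np.ndarray,
    covariates=None,
    markers: list[str] | None = None,
    kinship: np.ndarray | None = None,
) -> PleiotropyResult:
    """Profile-likelihood surface over ordered position pairs and the
    pleiotropy-vs-linkage log10 likelihood-ratio statistic."""
    Y, C, G, _ = _prepare(y1, y2, dosage_interval, covariates, kinship)
    grid = _SurGrid(C, G)
    stat, surface, extras = grid.lrt(Y)
    amax = np.unravel_index(np.argmax(surface), surface.shape)
    return PleiotropyResult(
        surface=surface - surface.max(),
        lrt=stat,
        argmax=(int(amax[0]), int(amax[1])),
        diag_argmax=int(np.argmax(np.diag(surface))),
        markers=list(markers) if markers is not None else [str(i) for i in range(surface.shape[0])],
        n_nonconverged=0 if extras["converged"] else 1,
    )


def bootstrap_pvalue(
    y1,
    y2,
    dosage_interval: np.ndarray,
    covariates=None,
    B: int = 1000,
    seed: int | None = None,
    markers: list[str] | None = None,
    kinship: np.ndarray | None = None,
) -> PleiotropyResult:
    """Parametric-bootstrap p for the pleiotropy test.

    Bootstrap data are simulated from the fitted pleiotropic null: bivariate
    normal residuals (the MLE 2x2 covariance) around the fitted means at the
    diagonal argmax.  A replicate whose profile fit fails to converge or
    errors is counted as exceeding the observed statistic (conservative) and
    reported in ``n_nonconverged``, never dropped.
    """
    if B < 50:
        raise ValueError("B must be at least 50")
    rng = np.random.default_rng(seed)
    Y, C, G, _ = _prepare(y1, y2, dosage_interval, covariates, kinship)
    n = Y.shape[0]
    grid = _SurGrid(C, G)
    lrt_obs, surface, _ = grid.lrt(Y)
    amax = np.unravel_index(np.argmax(surface), surface.shape)
    d = int(np.argmax(np.diag(surface)))
    # refit the pleiotropic null at the diagonal argmax (exact multivariate
    # regression MLE since both equations share the design)
    Z = np.column_stack([C, G[:, d, :]])
    Bhat, _, _, _ = np.linalg.lstsq(Z, Y, rcond=None)
    mu = Z @ Bhat
    resid = Y - mu
    Sigma = (resid.T @ resid) / n
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular residual covariance under the pleiotropic null") from exc
    exceed = 0
    n_bad = 0
    for _ in range(B):
        E = rng.standard_normal((n, 2)) @ L.T
        try:
            lrt_b, _, extras = grid.lrt(mu + E)
            if not extras["converged"]:
                n_bad += 1
                exceed += 1
                continue
        except (np.linalg.LinAlgError, ValueError):
            n_bad += 1
            exceed += 1
            continue
        if lrt_b >= lrt_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (B + 1.0)
    return PleiotropyResult(
        surface=surface - surface.max(),
        lrt=lrt_obs,
        argmax=(int(amax[0]), int(amax[1])),
        diag_argmax=d,
        markers=list(markers) if markers is not None else [str(i) for i in range(surface.shape[0])],
        B=B,
        pvalue=float(p),
        n_nonconverged=n_bad,
    )
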
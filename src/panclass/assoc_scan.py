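"""Single-marker association with PCA covariates, and the iterative
remove-and-rescan procedure for resolving multiple linked signals.

The per-marker test is ordinary least squares of the trait on dosage plus
principal-component covariates plus an intercept; the published multi-locus
GWAS models this wraps around correct for LD and kinship internally, so the
OLS test here is a documented, pluggable stand-in — the contribution of this
module is the iteration-and-removal loop, not the test's internals.  Missing
dosages are dropped per test (pairwise-complete deletion), never imputed,
so the test stays exact at panel scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import RankError
from .vcf_markers import MISSING, MarkerSet, minor_allele_frequency

__all__ = [
    "AssociationResult",
    "ScanRegion",
    "pca_covariates",
    "single_marker_test",
    "iterative_region_scan",
    "ScanOutcome",
]


@dataclass(frozen=True)
class AssociationResult:
    """One marker's association summary: p, MAF, per-allele effect, PVE.

    ``effect`` is the OLS dosage coefficient (trait units per alt-allele
    copy; positive means alt carriers score higher).  ``pve`` is 100 x R²
    of the dosage-only regression on the covariate-residualised trait.
    """

    marker_id: str
    p_value: float
    maf: float
    effect: float
    pve: float

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value must be in (0,1], got {self.p_value}")
        if not 0.0 <= self.pve <= 100.0:
            raise ValueError(f"pve must be in [0,100], got {self.pve}")


@dataclass(frozen=True)
class ScanRegion:
    """A 1-based inclusive genomic interval the scan's stopping rule watches."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass(frozen=True)
class ScanOutcome:
    """Results of the iterative scan, in discovery order."""

    results: tuple[AssociationResult, ...]
    truncated: bool  # True when max_iter stopped the loop, not convergence


def pca_covariates(ms: MarkerSet, n_components: int = 4) -> np.ndarray:
    """Principal components of the centered dosage matrix.

    Missing dosages are mean-imputed per marker before the decomposition.
    Returns an (n_accessions, n_components) score matrix ordered by
    decreasing explained variance.  Four components is the default the
    population structure of a diversity panel typically needs.
    """
    n_acc = ms.n_accessions
    if n_acc < n_components + 1:
        raise RankError(f"{n_acc} accessions cannot support {n_components} PCs")
    if len(ms) < n_components:
        raise RankError(f"{len(ms)} markers cannot support {n_components} PCs")
    X = ms.dosage_matrix().astype(float).T  # accessions x markers
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    X -= X.mean(axis=0)
    if not np.any(X):
        raise RankError("dosage matrix is constant; no principal axes exist")
    # economy SVD: scores = U * S
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, S.size)
    scores = U[:, :k] * S[:k]
    if k < n_components:
        raise RankError(f"matrix rank {k} < requested {n_components} components")
    return scores


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares fit; returns (beta, se, rss). X includes the intercept."""
    n, p = X.shape
    if n <= p:
        raise RankError(f"n={n} observations <= p={p} parameters")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise RankError("design matrix is rank deficient")
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    return beta, se, rss


def single_marker_test(
    d: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    marker_id: str = "",
) -> AssociationResult | None:
    """OLS association of one marker's dosage with a trait.

    Accessions missing the dosage or the trait are dropped.  Returns None
    (skip flag) for markers monomorphic after deletion.  The p-value is the
    two-sided t-test of the dosage coefficient.
    """
    d = np.asarray(d, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if d.shape[0] != trait.shape[0]:
        raise ValueError("dosage and trait lengths differ")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.shape[0] != d.shape[0]:
            raise ValueError("covariate rows do not match accessions")

    ok = (d != MISSING) & ~np.isnan(trait)
    d_ok = d[ok]
    y = trait[ok]
    if d_ok.size == 0 or np.all(d_ok == d_ok[0]):
        return None  # monomorphic after deletion: flagged by skipping
    n = d_ok.size

    cols = [np.ones(n), d_ok]
    if covariates is not None and covariates.shape[1] > 0:
        cols.append(covariates[ok])
    X = np.column_stack(cols)
    beta, se, _ = _ols(y, X)
    dof = n - X.shape[1]
    t = beta[1] / se[1] if se[1] > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t), dof))
    p = max(p, np.finfo(float).tiny)  # keep p in (0, 1]

    # PVE: R^2 of the dosage-only model on the covariate-residualised trait
    if covariates is not None and covariates.shape[1] > 0:
        Z = np.column_stack([np.ones(n), covariates[ok]])
        bz, _, _ = _ols(y, Z)
        y_res = y - Z @ bz
    else:
        y_res = y - y.mean()
    W = np.column_stack([np.ones(n), d_ok])
    bw, _, rss_w = _ols(y_res, W)
    tss = float((y_res - y_res.mean()) @ (y_res - y_res.mean()))
    r2 = 0.0 if tss == 0.0 else max(0.0, 1.0 - rss_w / tss)

    dd = d_ok[d_ok != MISSING]
    p_alt = float(dd.sum()) / (2 * dd.size)
    return AssociationResult(
        marker_id=marker_id,
        p_value=min(p, 1.0),
        maf=min(p_alt, 1.0 - p_alt),
        effect=float(beta[1]),
        pve=min(100.0, 100.0 * r2),
    )


def iterative_region_scan(
    ms: MarkerSet,
    trait: np.ndarray,
    region: ScanRegion,
    covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    max_iter: int = 10,
    test: Callable[..., AssociationResult | None] = single_marker_test,
) -> ScanOutcome:
    """Iterative remove-and-rescan over a region of linked signals.

    Each round tests every remaining marker (genome-wide), applies a
    Bonferroni threshold of ``alpha / n_tested``, and — if the most
    significant marker falling inside ``region`` passes — records it,
    removes it from the panel, and rescans.  The loop stops when no
    in-region marker is significant or after ``max_iter`` rounds (the
    outcome is then flagged truncated).  Testing stays genome-wide while
    the stopping rule is region-restricted, mirroring repeated full GWAS
    runs read out over one locus.
    """
    remaining = list(ms.markers)
    found: list[AssociationResult] = []
    truncated = False
    for _ in range(max_iter):
        scored = []
        n_tested = 0
        for m in remaining:
            res = test(m.dosages, trait, covariates, marker_id=m.id)
            if res is None:
                continue
            n_tested += 1
            if region.contains(m.chrom, m.pos):
                scored.append((res.p_value, m.pos, m.id, res, m))
        if not scored or n_tested == 0:
            break
        threshold = alpha / n_tested
        scored.sort(key=lambda t: (t[0], t[1], t[2]))
        best = scored[0]
        if best[0] > threshold:
            break
        found.append(best[3])
        remaining.remove(best[4])
    else:
        truncated = True
    return ScanOutcome(results=tuple(found), truncated=truncated)
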
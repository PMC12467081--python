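"""Linkage-disequilibrium decay: pairwise r², distance-binned curves, and
the linked-region half-width used to size candidate-gene intervals.

r² is the squared Pearson correlation of genotype dosages over
pairwise-complete accessions (the composite, PLINK-style estimator);
haplotype-phase EM estimation is deliberately not used because the
dosage encoding collapses phase.  Missing genotypes are handled by
pairwise deletion.  Inter-chromosome pairs carry no physical distance and
never enter the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError
from .vcf_markers import MISSING, MarkerSet

__all__ = ["DecayCurve", "HalfWidth", "pairwise_r2", "decay_curve", "linked_region_halfwidth"]


@dataclass(frozen=True)
class DecayCurve:
    """Mean r² per physical-distance bin.

    ``bin_edges`` has one more entry than ``mean_r2``; bin i covers
    [edges[i], edges[i+1]) in bp.  Bins with no pairs hold NaN in
    ``mean_r2`` (undefined, not zero).
    """

    bin_edges: np.ndarray
    mean_r2: np.ndarray
    pair_counts: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.bin_edges, dtype=float)
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.mean_r2)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "mean_r2": self.mean_r2,
                "n_pairs": self.pair_counts,
            }
        )


@dataclass(frozen=True)
class HalfWidth:
    """Result of the decay-threshold crossing search."""

    halfwidth_bp: int
    crossed: bool  # False: curve never fell below the threshold


def pairwise_r2(d1: np.ndarray, d2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Pairs where either vector is missing are deleted.  A vector that is
    constant after deletion yields r² = 0 (monomorphic sites carry no
    linkage information; returning 0 keeps them from poisoning bins).
    """
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    if d1.shape != d2.shape:
        raise ValueError("dosage vectors differ in length")
    ok = (d1 != MISSING) & (d2 != MISSING)
    if int(ok.sum()) < 2:
        raise InsufficientDataError(
            f"only {int(ok.sum())} pairwise-complete accessions; need >= 2"
        )
    x = d1[ok].astype(float)
    y = d2[ok].astype(float)
    x -= x.mean()
    y -= y.mean()
    vx = float(x @ x)
    vy = float(y @ y)
    if vx == 0.0 or vy == 0.0:
        return 0.0
    c = float(x @ y)
    return c * c / (vx * vy)


def decay_curve(ms: MarkerSet, max_dist: int, bin_width: int) -> DecayCurve:
    """Bin r² of all intra-chromosome marker pairs by physical distance.

    Every pair with 1 <= distance <= max_dist contributes to the bin of its
    distance.  Pairs with < 2 complete observations are skipped.
    """
    if bin_width <= 0 or max_dist < bin_width:
        raise ValueError("need max_dist >= bin_width > 0")
    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)

    by_chrom: dict[str, list] = {}
    for m in ms:
        by_chrom.setdefault(m.chrom, []).append(m)

    for group in by_chrom.values():
        pos = np.array([m.pos for m in group])
        mat = np.vstack([m.dosages for m in group]).astype(float)
        mat[mat == MISSING] = np.nan
        n = len(group)
        for i in range(n):
            # markers are position-sorted, so scan right until out of range
            for j in range(i + 1, n):
                dist = int(pos[j] - pos[i])
                if dist > max_dist:
                    break
                xi, xj = mat[i], mat[j]
                ok = ~np.isnan(xi) & ~np.isnan(xj)
                if ok.sum() < 2:
                    continue
                x = xi[ok] - xi[ok].mean()
                y = xj[ok] - xj[ok].mean()
                vx = float(x @ x)
                vy = float(y @ y)
                r2 = 0.0 if vx == 0.0 or vy == 0.0 else float(x @ y) ** 2 / (vx * vy)
                b = min((dist - 1) // bin_width, n_bins - 1) if dist > 0 else 0
                # dist == bin edge goes to the lower bin via the -1 shift;
                # bin i therefore covers (i*w, (i+1)*w]
                sums[b] += r2
                counts[b] += 1

    mean = np.full(n_bins, np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    return DecayCurve(bin_edges=edges, mean_r2=mean, pair_counts=counts)


def linked_region_halfwidth(curve: DecayCurve, threshold: float) -> HalfWidth:
    """Distance at which mean r² first drops below ``threshold``.

    Returns the left edge of the first bin with defined mean r² below the
    threshold.  If no bin crosses, returns the curve's maximum distance
    with ``crossed=False`` so callers can widen the window.
    """
    if curve.n_bins == 0:
        raise ValueError("empty decay curve")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    for i in range(curve.n_bins):
        r2 = curve.mean_r2[i]
        if np.isnan(r2):
            continue
        if r2 < threshold:
            return HalfWidth(halfwidth_bp=int(curve.bin_edges[i]), crossed=True)
    return HalfWidth(halfwidth_bp=int(curve.bin_edges[-1]), crossed=False)
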
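"""Circular statistics, divergent-torsion screening, and PCA.

Torsion angles are circular variables, so plain arithmetic means and PCA on
raw degrees are wrong near the ±180° seam.  This module provides circular
means/differences, a screen for torsions whose circular mean in a mutant
deviates from the wild type by more than a threshold (with a permutation
test guarding against broad, overlapping distributions), and the standard
dihedral-PCA construction: each torsion θ enters the feature matrix as the
pair (cos θ, sin θ).  For the three catalytic geometry variables the feature
matrix instead holds z-scored raw values, since distances (Å) and an angle
(degrees) live on different scales.

A single PCA is always fitted on the pooled frames of all variants, and
every variant is projected with the same loadings — the whole point is that
the projections of different trajectories are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "circular_mean",
    "circular_diff",
    "select_divergent_torsions",
    "build_feature_matrix",
    "fit_project_pca",
]

log = logging.getLogger(__name__)


def circular_mean(series_deg) -> float:
    """Circular mean of angles in degrees, in (−180, 180].

    NaN (undefined) when the resultant vector length is numerically zero,
    i.e. the sample is uniform on the circle.
    """
    a = np.radians(np.asarray(series_deg, dtype=float))
    a = a[~np.isnan(a)]
    if a.size == 0:
        raise ValueError("empty series")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if np.hypot(s, c) < 1e-12:
        log.warning("circular mean undefined: zero resultant length")
        return float("nan")
    mean = np.degrees(np.arctan2(s, c))
    return float(mean if mean > -180.0 else mean + 360.0)


def circular_diff(a_deg: float, b_deg: float) -> float:
    """Minimal signed difference a − b on the circle, in (−180, 180]."""
    d = (float(a_deg) - float(b_deg)) % 360.0
    if d > 180.0:
        d -= 360.0
    elif d == 180.0:
        d = 180.0
    return d


def _perm_pvalue(
    wt: np.ndarray, mut: np.ndarray, observed: float, n_perm: int, rng
) -> float:
    """Permutation p-value for the absolute circular-mean difference."""
    pooled = np.radians(np.concatenate([wt, mut]))
    z = np.exp(1j * pooled)
    n, n1 = z.size, wt.size
    total = z.sum()
    # n_perm random label permutations, vectorized
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    sel = np.take(z, order[:, :n1])
    s1 = sel.sum(axis=1)
    s2 = total - s1
    diff = np.degrees(np.angle(s1 / np.abs(s1) * np.conj(s2 / np.abs(s2))))
    stat = np.abs(diff)
    return float((1 + np.sum(stat >= observed)) / (n_perm + 1))


def select_divergent_torsions(
    series_by_variant: dict[str, pd.DataFrame],
    wt_id: str,
    threshold: float = 36.0,
    alpha: float = 0.001,
    n_perm: int = 10_000,
    seed: int = 0,
    *,
    thin: int = 10,
) -> set[str]:
    """Torsions whose circular mean in at least one mutant deviates from the
    wild type by more than ``threshold`` degrees, at permutation significance
    ``alpha``.

    Frames are thinned by ``thin`` before the permutation test to blunt the
    serial correlation of trajectory frames.  Deterministic given ``seed``.
    """
    if wt_id not in series_by_variant:
        raise ValueError(f"wild-type id {wt_id!r} not among variants")
    wt_df = series_by_variant[wt_id]
    labels = list(wt_df.columns)
    for vid, df in series_by_variant.items():
        if list(df.columns) != labels:
            raise ValueError(f"variant {vid!r} has mismatched torsion labels")
    rng = np.random.default_rng(seed)
    selected: set[str] = set()
    for label in labels:
        wt_vals = wt_df[label].to_numpy()[::thin]
        wt_mean = circular_mean(wt_vals)
        for vid, df in series_by_variant.items():
            if vid == wt_id:
                continue
            mut_vals = df[label].to_numpy()[::thin]
            diff = abs(circular_diff(circular_mean(mut_vals), wt_mean))
            if not diff > threshold:
                continue
            if alpha >= 1.0:
                selected.add(label)
                break
            p = _perm_pvalue(wt_vals, mut_vals, diff, n_perm, rng)
            if p < alpha:
                selected.add(label)
                break
    return selected


def build_feature_matrix(
    mode: str,
    inputs: dict[str, pd.DataFrame],
    *,
    subset: set[str] | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Assemble the frames × features matrix for PCA.

    ``mode='dihedral'``: inputs are per-variant torsion tables in degrees;
    each torsion contributes a cos and a sin column.  ``subset`` optionally
    restricts to selected torsion labels.

    ``mode='geometric'``: inputs are per-variant geometry tables; columns are
    z-scored over the pooled frames of all variants (``standardize=False``
    keeps raw units).

    Rows are indexed by (variant, frame).  Frames containing NA are dropped
    per variant (logged); all variants are then trimmed to the common frame
    count so that downstream occupancy histograms share N.
    """
    if mode not in ("dihedral", "geometric"):
        raise ValueError(f"unknown mode {mode!r}")
    ref_cols: list[str] | None = None
    cleaned: dict[str, pd.DataFrame] = {}
    for vid, df in inputs.items():
        if subset is not None:
            missing = set(subset) - set(df.columns)
            if missing:
                raise ValueError(f"variant {vid!r} lacks torsions {sorted(missing)}")
            df = df[[c for c in df.columns if c in subset]]
        if ref_cols is None:
            ref_cols = list(df.columns)
        elif list(df.columns) != ref_cols:
            raise ValueError(f"variant {vid!r} has inconsistent feature labels")
        n0 = len(df)
        df = df.dropna()
        if len(df) < n0:
            log.info("variant %s: dropped %d NA frame(s)", vid, n0 - len(df))
        cleaned[vid] = df
    n_common = min(len(df) for df in cleaned.values())
    if n_common == 0:
        raise ValueError("no complete frames left after NA removal")
    blocks = []
    for vid, df in cleaned.items():
        df = df.iloc[:n_common]
        if mode == "dihedral":
            rad = np.radians(df.to_numpy(dtype=float))
            data = np.empty((len(df), 2 * rad.shape[1]))
            data[:, 0::2] = np.cos(rad)
            data[:, 1::2] = np.sin(rad)
            cols = [f"{c}:{f}" for c in df.columns for f in ("cos", "sin")]
            block = pd.DataFrame(data, columns=cols)
        else:
            block = df.reset_index(drop=True).astype(float)
        block.index = pd.MultiIndex.from_product(
            [[vid], range(len(block))], names=["variant", "frame"]
        )
        blocks.append(block)
    fm = pd.concat(blocks)
    if mode == "geometric" and standardize:
        fm = (fm - fm.mean()) / fm.std(ddof=1)
    return fm


@dataclass
class PCAResult:
    """Single PCA fit over the pooled frames of all variants."""

    mean: pd.Series
    components: pd.DataFrame  # (k, p), rows orthonormal loadings
    eigenvalues: np.ndarray  # non-increasing variances
    projections: pd.DataFrame  # (variant, frame) × PC1..PCk

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def variant_means(self) -> pd.DataFrame:
        """Arithmetic mean of the projections per variant (for 2-D maps of
        the variant cloud centres)."""
        return self.projections.groupby(level="variant", sort=False).mean()


def fit_project_pca(fm: pd.DataFrame) -> PCAResult:
    """PCA by eigendecomposition of the pooled covariance matrix.

    Every variant is projected with the same loadings.  Sign convention:
    the largest-magnitude element of each loading is positive.
    """
    X = fm.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = np.cov(Xc, rowvar=False, ddof=1)
    if not np.any(np.diag(cov) > 0):
        raise ValueError("degenerate input: zero total variance")
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.where(np.abs(w) < 1e-12, np.abs(w), w)  # clip tiny negative noise
    # sign convention
    for j in range(v.shape[1]):
        if v[np.argmax(np.abs(v[:, j])), j] < 0:
            v[:, j] = -v[:, j]
    proj = Xc @ v
    k = v.shape[1]
    pc_cols = [f"PC{i+1}" for i in range(k)]
    return PCAResult(
        mean=pd.Series(mean, index=fm.columns),
        components=pd.DataFrame(v.T, index=pc_cols, columns=fm.columns),
        eigenvalues=w,
        projections=pd.DataFrame(proj, index=fm.index, columns=pc_cols),
    )
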
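"""End-to-end trajectory classification: features → PCA → overlap tree → calls.

Thin orchestration over the analysis modules, used by the command-line
interface and by recovery experiments: given per-variant torsion or geometry
time series, run one pooled PCA, histogram every variant's (PC1, PC2) cloud
on a shared grid, build the Bhattacharyya/UPGMA tree and classify variants
relative to the wild type.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dimred import (PCAResult, build_feature_matrix, fit_project_pca,
                     select_divergent_torsions)
from .trajectory_clustering import (CountGrid, DistanceMatrix, GridSpec,
                                    TreeNode, bhattacharyya_distance_matrix,
                                    classify_by_branch, grid_histogram, upgma)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    feature_matrix: pd.DataFrame
    pca: PCAResult
    grid: GridSpec
    count_grids: dict[str, CountGrid]
    distances: DistanceMatrix
    tree: TreeNode
    calls: dict[str, str]
    selected_torsions: set[str] | None = None


def run_pipeline(
    mode: str,
    series_by_variant: dict[str, pd.DataFrame],
    wt_id: str = "WT",
    *,
    rule: str = "distal_affected",
    nx: int = 10,
    ny: int = 10,
    threshold: float = 36.0,
    alpha: float = 0.001,
    seed: int = 0,
    standardize: bool = True,
) -> PipelineResult:
    """Classify variants from per-variant time series.

    ``mode`` is ``geometric`` (z-scored catalytic-geometry variables),
    ``dihedral`` (all torsions, sin/cos encoded) or ``dihedral-divergent``
    (torsions first screened for a >``threshold``° circular-mean deviation
    from the wild type at permutation significance ``alpha``).
    """
    selected: set[str] | None = None
    if mode == "dihedral-divergent":
        selected = select_divergent_torsions(
            series_by_variant, wt_id, threshold=threshold, alpha=alpha, seed=seed
        )
        if not selected:
            raise ValueError("no torsion passed the divergence screen")
        fm = build_feature_matrix("dihedral", series_by_variant, subset=selected)
    elif mode == "dihedral":
        fm = build_feature_matrix("dihedral", series_by_variant)
    elif mode == "geometric":
        fm = build_feature_matrix("geometric", series_by_variant,
                                  standardize=standardize)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pca = fit_project_pca(fm)
    grid, grids = grid_histogram(pca.projections, nx=nx, ny=ny)
    dm = bhattacharyya_distance_matrix(list(grids.values()))
    tree = upgma(dm)
    calls = classify_by_branch(tree, wt_id, rule, distances=dm)
    return PipelineResult(fm, pca, grid, grids, dm, tree, calls, selected)
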
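"""Count analytics: decoy signal tuning, fold changes, clustering.

Because sequencing reads are a finite resource, highly expressed
targets oversample the pool at the expense of rare ones.  Signal is
tuned down per probe set by titrating decoy oligos -- probe analogs
that compete for template but cannot be amplified -- while keeping the
total (always saturating) probe concentration constant.  The observed
fold reduction tracks the decoy dilution for acceptor decoys and is
amplified by an empirical ~3-4x factor for (unphosphorylated) donor
decoys; decoying both multiplies the two effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "DecoyModelConfig",
    "DecoyPlanEntry",
    "mix_ratio",
    "predicted_fold_reduction",
    "combined_fold_reduction",
    "recommend_mix_ratios",
    "normalize_and_fold_change",
    "standardize_rows",
    "standardize_and_cluster",
    "ClusterResult",
]

DECOY_KINDS = ("acceptor", "donor", "both")


@dataclass(frozen=True)
class DecoyModelConfig:
    """donor_amplification_factor: how much stronger a donor decoy
    suppresses ligation than its dilution alone predicts (empirically
    ~3-4x; the unphosphorylated decoy outcompetes the charged donor)."""

    donor_amplification_factor: float = 3.5

    def __post_init__(self) -> None:
        if self.donor_amplification_factor < 1:
            raise ValueError("donor_amplification_factor must be >= 1")


@dataclass(frozen=True)
class DecoyPlanEntry:
    """Decoy prescription for one probe set."""

    set_id: str
    kind: str  # acceptor | donor | both
    mix_ratio: float
    predicted_fold_reduction: float


def mix_ratio(authentic_fraction: float) -> float:
    """Mix ratio = total probe / authentic probe = 1 / authentic fraction.

    A 1:3 authentic:decoy mix has authentic fraction 0.25, mix ratio 4.
    """
    if not (0 < authentic_fraction <= 1):
        raise ValueError("authentic fraction must be in (0, 1]")
    return 1.0 / authentic_fraction


def predicted_fold_reduction(
    kind: str,
    ratio: float,
    cfg: DecoyModelConfig = DecoyModelConfig(),
) -> float:
    """Predicted fold reduction in ligation product for one decoy kind.

    acceptor -> ratio; donor -> ratio * donor_amplification_factor;
    both -> product of the two single-kind predictions.
    A ratio of 1 (no decoy) predicts no reduction for any kind.
    """
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind {kind!r}")
    if ratio < 1:
        raise ValueError("mix ratio must be >= 1")
    if ratio == 1.0:
        return 1.0
    if kind == "acceptor":
        return ratio
    if kind == "donor":
        return ratio * cfg.donor_amplification_factor
    return ratio * (ratio * cfg.donor_amplification_factor)


def combined_fold_reduction(acceptor_fold: float, donor_fold: float) -> float:
    """Fold reduction when both probes are decoyed, given the two
    separately observed (or predicted) component reductions."""
    return acceptor_fold * donor_fold


def recommend_mix_ratios(
    pilot_counts: pd.Series,
    target_share: float,
    cfg: DecoyModelConfig = DecoyModelConfig(),
    kind: str = "acceptor",
    cap: float | None = None,
    grid: list[float] | None = None,
    correct_renormalization: bool = True,
) -> list[DecoyPlanEntry]:
    """Plan acceptor decoys so no probe exceeds *target_share* of reads.

    The naive prescription ratio = share / target ignores that read
    shares renormalize once the oversampled probes shrink; with
    correct_renormalization (default) ratios are solved so decoyed
    probes land on the target share exactly in expectation.  cap bounds
    ratios; grid snaps each ratio up to the nearest pipettable value.
    Returns entries for every probe (ratio 1 for the untreated ones);
    an all-zero pilot yields a no-op plan.
    """
    if not (0 < target_share < 1):
        raise ValueError("target share must be in (0, 1)")
    total = float(pilot_counts.sum())
    ids = list(pilot_counts.index)
    if total == 0:
        return [DecoyPlanEntry(i, kind, 1.0, 1.0) for i in ids]
    share = pilot_counts / total
    over = set(share.index[share > target_share])
    if correct_renormalization and over:
        # final shares always sum to 1, so every probe <= target needs
        # target >= 1/n
        if target_share * len(ids) < 1:
            raise ValueError("target share below 1/n_probes: infeasible")
        while True:
            under = [i for i in ids if i not in over]
            u = float(share[under].sum()) if under else 0.0
            if not under:
                break
            scale = (1 - len(over) * target_share) / u
            grown = {i for i in under if share[i] * scale > target_share}
            if not grown:
                break
            over |= grown
    entries = []
    under = [i for i in ids if i not in over]
    u = float(share[under].sum()) if under else 0.0
    for i in ids:
        if i not in over:
            entries.append(DecoyPlanEntry(i, kind, 1.0, 1.0))
            continue
        if correct_renormalization and u > 0:
            r = float(share[i]) * (1 - len(over) * target_share) / (target_share * u)
        else:
            r = float(share[i]) / target_share
        r = max(r, 1.0)
        if cap is not None:
            r = min(r, cap)
        if grid is not None:
            above = [g for g in sorted(grid) if g >= r]
            r = above[0] if above else max(grid)
        entries.append(
            DecoyPlanEntry(i, kind, r, predicted_fold_reduction(kind, r, cfg))
        )
    return entries


def normalize_and_fold_change(
    counts_a: pd.Series,
    counts_b: pd.Series,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-probe fold change of condition A over condition B.

    Each count gets the pseudocount, is normalized to its sample's raw
    total, and the simple ratio is taken:
    fc = ((a + 1) / sum(A)) / ((b + 1) / sum(B)).
    """
    if not counts_a.index.equals(counts_b.index):
        counts_b = counts_b.reindex(counts_a.index)
        if counts_b.isna().any():
            raise ValueError("probe rows of the two conditions do not match")
    ta, tb = float(counts_a.sum()), float(counts_b.sum())
    if ta == 0 or tb == 0:
        raise ValueError("zero column total: cannot normalize")
    return ((counts_a + pseudocount) / ta) / ((counts_b + pseudocount) / tb)


def standardize_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row (mean 0, population sd 1); constant rows are
    excluded with a warning since they carry no clustering signal."""
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=0)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant row(s): "
            f"{list(matrix.index[constant])}"
        )
        matrix = matrix.loc[~constant]
        means, sds = means[~constant], sds[~constant]
    return matrix.sub(means, axis=0).div(sds, axis=0)


@dataclass
class ClusterResult:
    matrix: pd.DataFrame  # standardized, rows/columns in dendrogram order
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    row_newick: str
    col_newick: str


def _to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_dist):
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return (
            f"({rec(node.left, node.dist)},{rec(node.right, node.dist)})"
            f":{length:.6g}"
        )

    return rec(tree, tree.dist) + ";"


def standardize_and_cluster(matrix: pd.DataFrame) -> ClusterResult:
    """Standardize rows then hierarchically cluster with Euclidean
    distance, columns (samples) first and then rows (probe sets).

    Average linkage; leaf order is scipy's deterministic ordering.
    Requires at least 2 non-constant rows and 2 columns.
    """
    z = standardize_rows(matrix)
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("need at least 2 non-constant rows and 2 columns")
    col_link = hierarchy.linkage(pdist(z.T.to_numpy()), method="average")
    col_order = [z.columns[i] for i in hierarchy.leaves_list(col_link)]
    row_link = hierarchy.linkage(pdist(z.to_numpy()), method="average")
    row_order = [z.index[i] for i in hierarchy.leaves_list(row_link)]
    return ClusterResult(
        matrix=z.loc[row_order, col_order],
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=row_order,
        col_order=col_order,
        row_newick=_to_newick(row_link, list(z.index)),
        col_newick=_to_newick(col_link, list(z.columns)),
    )
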
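"""Condition-dependent activity quantification from two-channel volumes.

Whole-brain immediate-early-gene (c-fos) labelling is imaged together
with a pan-neuronal reference channel (elavl3) in the same registered
volume.  Because signal drops with tissue depth, the activity channel
is divided voxelwise by the reference channel before quantification;
the depth attenuation affects both channels equally and cancels in the
ratio.  Bulk signal per manually drawn activity cluster is the mean
normalized intensity over the cluster's voxels; conditions are compared
against the no-stimulus baseline with Cohen's d (pooled-SD convention,
negative = below baseline) and two-tailed t-tests, Bonferroni-corrected
within each cluster's family of three comparisons (alpha/3 tiers).
Effect-size profiles across conditions are grouped by average-linkage
Euclidean hierarchical clustering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "VolumePair",
    "EffectMatrix",
    "normalize_activity",
    "bulk_cluster_signal",
    "cohens_d",
    "condition_effects",
    "effect_dendrogram",
    "linkage_to_newick",
]

CONDITIONS = ("no-stimulus", "continuous", "bout-like", "conspecific")


@dataclass
class VolumePair:
    """Activity (c-fos) and reference (elavl3) volumes for one animal."""

    activity: np.ndarray
    reference: np.ndarray
    animal_id: str = ""
    condition: str = "no-stimulus"

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.activity.shape != self.reference.shape:
            raise ValueError("activity and reference volumes must have identical shapes")
        if np.any(self.activity < 0) or np.any(self.reference < 0):
            raise ValueError("intensities must be non-negative")


def normalize_activity(pair: VolumePair, floor_frac: float = 0.01,
                       brain_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Voxelwise activity / reference ratio; unusable voxels become NaN.

    Voxels whose reference intensity is below ``floor_frac`` of the in-brain
    median reference are masked out (NaN) rather than producing unbounded
    ratios; downstream means ignore them.  No smoothing is applied — the
    unfiltered reference is the quantification path.
    """
    ref = pair.reference
    inside = brain_mask if brain_mask is not None else np.ones(ref.shape, dtype=bool)
    ref_in = ref[inside]
    if not np.any(ref_in > 0):
        raise ValueError("reference channel is zero everywhere in the brain")
    floor = floor_frac * np.median(ref_in[ref_in > 0])
    ok = inside & (ref >= floor)
    out = np.full(ref.shape, np.nan)
    out[ok] = pair.activity[ok] / ref[ok]
    return out


def bulk_cluster_signal(normalized: np.ndarray,
                        masks: Mapping[str, np.ndarray]) -> pd.Series:
    """Mean normalized signal over each activity cluster's valid voxels."""
    out = {}
    for name, m in masks.items():
        vals = normalized[np.asarray(m, dtype=bool)]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"cluster {name!r} has no usable voxels", RuntimeWarning)
            out[name] = np.nan
        else:
            out[name] = float(vals.mean())
    return pd.Series(out)


def cohens_d(group: np.ndarray, baseline: np.ndarray) -> float:
    """Cohen's d: difference of means over the pooled standard deviation.

    Positive when ``group`` exceeds ``baseline``; NaN when the pooled SD
    is zero.
    """
    g = np.asarray(group, dtype=float)
    b = np.asarray(baseline, dtype=float)
    n1, n0 = len(g), len(b)
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = math.sqrt(((n1 - 1) * g.var(ddof=1) + (n0 - 1) * b.var(ddof=1))
                       / (n1 + n0 - 2))
    if pooled == 0:
        return math.nan
    return float((g.mean() - b.mean()) / pooled)


@dataclass
class EffectMatrix:
    """Cluster x condition effect sizes vs baseline, with test results."""

    d: pd.DataFrame              # Cohen's d
    p: pd.DataFrame              # two-tailed t-test p-values
    tier: pd.DataFrame           # 0-3 significance stars at alpha/3 thresholds
    baseline: str
    n_comparisons: int


def condition_effects(bulk: pd.DataFrame, conditions: pd.Series,
                      baseline: str = "no-stimulus", equal_var: bool = True,
                      alpha: float = 0.05) -> EffectMatrix:
    """Effect size and significance of each condition vs baseline, per cluster.

    ``bulk`` is animals x clusters; ``conditions`` labels each animal.  For
    every cluster and non-baseline condition: Cohen's d (identical groups
    give d = 0 and p = 1) and a two-tailed two-sample t-test (Student by
    default, Welch with ``equal_var=False``).  Significance tiers follow the
    Bonferroni family of the within-cluster comparisons: 1/2/3 stars at
    p < 0.05/m, 0.01/m, 0.001/m with m the number of conditions compared.
    """
    conditions = pd.Series(conditions)
    if baseline not in set(conditions):
        raise ValueError(f"baseline condition {baseline!r} not present")
    others = [c for c in pd.unique(conditions) if c != baseline]
    m = len(others)
    base_rows = bulk.loc[conditions[conditions == baseline].index]
    d = pd.DataFrame(index=bulk.columns, columns=others, dtype=float)
    p = pd.DataFrame(index=bulk.columns, columns=others, dtype=float)
    for cond in others:
        rows = bulk.loc[conditions[conditions == cond].index]
        if len(rows) < 2 or len(base_rows) < 2:
            raise ValueError(f"need >= 2 animals per group (condition {cond!r})")
        for cl in bulk.columns:
            g = rows[cl].dropna().to_numpy()
            b = base_rows[cl].dropna().to_numpy()
            if len(g) < 2 or len(b) < 2:
                d.loc[cl, cond] = np.nan
                p.loc[cl, cond] = np.nan
                continue
            d.loc[cl, cond] = cohens_d(g, b)
            if np.allclose(g, g[0]) and np.allclose(b, b[0]) and g[0] == b[0]:
                p.loc[cl, cond] = 1.0
            else:
                p.loc[cl, cond] = stats.ttest_ind(g, b, equal_var=equal_var).pvalue
    tier = pd.DataFrame(0, index=bulk.columns, columns=others, dtype=int)
    for stars, level in ((1, 0.05), (2, 0.01), (3, 0.001)):
        tier[p < level / m] = stars
    tier[p.isna()] = 0
    return EffectMatrix(d, p, tier, baseline, m)


def effect_dendrogram(effects: EffectMatrix | pd.DataFrame):
    """Average-linkage Euclidean clustering of effect-size profiles.

    Rows (clusters) with any undefined effect size are excluded (reported
    in the third return value).  Returns (linkage matrix, leaf labels in
    dendrogram order, dropped row labels); SciPy's linkage tie-breaking is
    deterministic for a fixed input order.
    """
    d = effects.d if isinstance(effects, EffectMatrix) else effects
    dropped = list(d.index[d.isna().any(axis=1)])
    kept = d.dropna(axis=0)
    if len(kept) < 2:
        if len(kept) == 1:
            return None, list(kept.index), dropped
        raise ValueError("need at least 2 complete rows to cluster")
    Z = hierarchy.linkage(kept.to_numpy(), method="average", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    return Z, [kept.index[i] for i in order], dropped


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"
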
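"""Transcriptional-wave detection and kinetic classification.

The treated time course is summarized as a time-point x time-point Pearson
correlation matrix (replicates averaged, correlation across genes). Waves
are contiguous blocks of post-baseline time points found by exhaustive
search over all segmentations, maximizing the mean within-block minus mean
between-block correlation — an explicit objective standing in for the
visual block structure of such matrices. Each differentially expressed gene
then receives a kinetic class (early / intermediate / late / bimodal /
unclassified) from where its fold-change profile peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

WAVE_ORDER_LABELS = ("early", "intermediate", "late")


@dataclass
class Wave:
    """A labeled contiguous block of time points with its member genes."""

    label: str
    time_points: tuple[float, ...]
    gene_set: set[str] = field(default_factory=set)


def timepoint_correlation_matrix(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    condition: str = "treated",
) -> pd.DataFrame:
    """Pearson correlation between time-point profiles across genes.

    Replicate columns are averaged per time point first; only samples of
    the requested condition (and without a perturbation label) enter.
    """
    keep = design["condition"] == condition
    pert = design["perturbation"]
    keep &= pert.map(lambda v: v is None or pd.isna(v))
    sub = design.loc[keep]
    if sub.empty:
        raise ValueError(f"no samples for condition {condition!r}")
    times = np.sort(sub["time_h"].unique())
    prof = pd.DataFrame(
        {t: expr[sub.index[sub["time_h"] == t]].mean(axis=1) for t in times}
    )
    sd = prof.std(axis=0)
    dead = [f"{t:g}" for t in times if sd[t] == 0]
    if dead:
        raise ValueError(f"zero-variance time point(s): {dead}")
    if prof.shape[0] < 2:
        raise ValueError("need >= 2 genes to correlate time points")
    corr = prof.corr(method="pearson")
    corr.index.name = corr.columns.name = "time_h"
    return corr


def _segmentations(n: int, k: int):
    """All ways to cut n ordered items into k contiguous non-empty blocks."""
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        yield [range(a, b) for a, b in zip(bounds, bounds[1:])]


def segmentation_objective(r: np.ndarray, blocks) -> float:
    """Mean within-block off-diagonal correlation minus mean between-block
    correlation; blocks with no within pair contribute nothing to the
    within mean."""
    n = r.shape[0]
    block_of = np.empty(n, int)
    for b, idx in enumerate(blocks):
        for i in idx:
            block_of[i] = b
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if block_of[i] == block_of[j] else between).append(r[i, j])
    w = float(np.mean(within)) if within else 0.0
    b = float(np.mean(between)) if between else 0.0
    return w - b


def segment_waves(corr: pd.DataFrame, n_waves: int = 3) -> list[Wave]:
    """Optimal contiguous segmentation of the post-baseline time points.

    t = 0 (the untreated baseline) is dropped if present. Ties are broken
    toward the earliest boundaries, making the output deterministic. With
    three waves the blocks are labeled early/intermediate/late in time
    order; otherwise wave_1..wave_k.
    """
    times = [float(t) for t in corr.index if float(t) > 0]
    if n_waves < 1:
        raise ValueError("n_waves must be >= 1")
    if len(times) < n_waves:
        raise ValueError(
            f"{len(times)} post-baseline time points cannot form {n_waves} waves"
        )
    r = corr.loc[times, times].to_numpy(float)
    best_obj, best_blocks = -np.inf, None
    for blocks in _segmentations(len(times), n_waves):
        obj = segmentation_objective(r, blocks)
        if obj > best_obj + 1e-12:  # strict improvement keeps earliest ties
            best_obj, best_blocks = obj, blocks
    labels = (
        WAVE_ORDER_LABELS
        if n_waves == 3
        else tuple(f"wave_{i + 1}" for i in range(n_waves))
    )
    return [
        Wave(label, tuple(times[i] for i in idx))
        for label, idx in zip(labels, best_blocks)
    ]


def assign_kinetic_class(
    profile: pd.Series,
    wave_calls: dict[str, bool],
    waves: list[Wave],
    lfc_threshold: float = 1.0,
) -> str:
    """Kinetic class of one consensus-DE gene.

    The peak criterion for a wave: |log2FC| >= threshold at some time point
    inside the wave AND the gene is significant in that wave. Bimodal means
    the criterion holds in early and late but not intermediate; otherwise
    the gene goes to the qualifying wave holding its largest |log2FC|;
    with no qualifying wave it is unclassified.
    """
    met: dict[str, bool] = {}
    peak: dict[str, float] = {}
    for w in waves:
        vals = profile.reindex(list(w.time_points)).abs()
        peak[w.label] = float(vals.max()) if len(vals) else 0.0
        met[w.label] = bool(wave_calls.get(w.label, False)) and peak[w.label] >= lfc_threshold
    labels = [w.label for w in waves]
    if (
        set(WAVE_ORDER_LABELS) <= set(labels)
        and met.get("early")
        and met.get("late")
        and not met.get("intermediate")
    ):
        return "bimodal"
    qualifying = [lb for lb in labels if met[lb]]
    if not qualifying:
        return "unclassified"
    return max(qualifying, key=lambda lb: (peak[lb], -labels.index(lb)))


def assign_kinetic_classes(
    log2fc: pd.DataFrame,
    wave_calls: pd.DataFrame,
    waves: list[Wave],
    de_genes: list[str],
    lfc_threshold: float = 1.0,
) -> pd.Series:
    """Vector version over all consensus-DE genes.

    ``log2fc`` is genes x time points (treated vs control), ``wave_calls``
    genes x wave labels (boolean per-wave significance).
    """
    out = {}
    for g in de_genes:
        calls = {lb: bool(wave_calls.loc[g, lb]) for lb in wave_calls.columns}
        out[g] = assign_kinetic_class(log2fc.loc[g], calls, waves, lfc_threshold)
    return pd.Series(out, name="kinetic_class")


def wave_gene_sets(classes: pd.Series, waves: list[Wave]) -> dict[str, list[str]]:
    """One gene set per wave; bimodal genes belong to early and late."""
    sets: dict[str, list[str]] = {w.label: [] for w in waves}
    for gene, cls in classes.items():
        if cls == "bimodal":
            for lb in ("early", "late"):
                if lb in sets:
                    sets[lb].append(gene)
        elif cls in sets:
            sets[cls].append(gene)
    return {lb: sorted(genes) for lb, genes in sets.items()}


def log2fc_profile(
    expr: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene treated-minus-control profile of mean log2 expression at
    each shared time point (replicates averaged)."""
    pert = design["perturbation"].map(lambda v: v is None or pd.isna(v))
    out = {}
    times = np.sort(design.loc[pert, "time_h"].unique())
    for t in times:
        tr = design.index[pert & (design["condition"] == "treated") & (design["time_h"] == t)]
        ct = design.index[pert & (design["condition"] == "control") & (design["time_h"] == t)]
        if len(tr) == 0 or len(ct) == 0:
            continue
        out[float(t)] = expr[tr].mean(axis=1) - expr[ct].mean(axis=1)
    return pd.DataFrame(out)
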
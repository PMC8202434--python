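"""Gene-set scoring: membership counts, candidate selection, module scores.

Membership scores count how many of a collection of gene sets (e.g. four
tumor-infiltrating-lymphocyte DE lists, or three interferon-stimulated-gene
catalogs) contain a gene; perturbation candidates are DE TFs shared by both
lineages that clear the ISG-score gate and show tumor or external-signature
support. Module scores follow the binned matched-control scheme: genes are
binned by average expression, each set gene draws control genes from its
own bin, and a sample's score is mean(set) - mean(controls).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MembershipScore:
    gene: str
    score: int
    source: str


@dataclass
class ModuleScore:
    """Per-sample score for one named gene set, with the scoring metadata
    needed to reproduce it."""

    scores: pd.Series
    set_name: str
    n_bins: int
    n_control: int
    seed: int
    control_genes: list[str] = field(default_factory=list)


def membership_score(
    gene: str, dataset_memberships: dict[str, list[str]], source: str = ""
) -> MembershipScore:
    """Count of datasets whose gene set contains the gene."""
    score = sum(1 for genes in dataset_memberships.values() if gene in set(genes))
    return MembershipScore(gene, score, source)


def select_candidates(
    de_tfs_a: set[str],
    de_tfs_b: set[str],
    isg_sets: dict[str, list[str]],
    til_sets: dict[str, list[str]],
    external_signatures: dict[str, list[str]] | None = None,
    min_isg_score: int = 1,
) -> pd.DataFrame:
    """Perturbation-candidate table.

    Candidates are TFs DE in both lineages whose ISG membership score
    reaches ``min_isg_score`` and that have either TIL support (score >= 1)
    or membership in any external signature. Every shared TF is returned
    with its criterion values and a boolean ``candidate`` column; rows are
    sorted by gene id, so the selection is order-invariant.
    """
    external_signatures = external_signatures or {}
    shared = sorted(de_tfs_a & de_tfs_b)
    rows = []
    for tf in shared:
        isg = membership_score(tf, isg_sets, "ISG").score
        til = membership_score(tf, til_sets, "TIL").score
        ext = sorted(
            name for name, genes in external_signatures.items() if tf in set(genes)
        )
        ok = isg >= min_isg_score and (til >= 1 or len(ext) > 0)
        rows.append((tf, isg, til, ";".join(ext), ok))
    return pd.DataFrame(
        rows, columns=["tf", "isg_score", "til_score", "external", "candidate"]
    ).set_index("tf")


def _expression_bins(avg: pd.Series, n_bins: int) -> pd.Series:
    """Equal-occupancy bins of genes by average expression (rank-based, so
    ties split deterministically)."""
    ranks = avg.rank(method="first") - 1
    return np.floor(ranks * n_bins / len(avg)).astype(int)


def module_score(
    expr: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_control: int = 100,
    seed: int = 0,
    set_name: str = "module",
) -> ModuleScore:
    """Bin-matched control module score per sample.

    ``expr`` is a dense genes x samples log-expression matrix. Set genes
    absent from the matrix are ignored; an empty intersection errors. For
    each set gene, up to ``n_control`` control genes are sampled without
    replacement (seeded) from the gene's expression bin excluding set
    genes; the per-sample score is the mean over set genes minus the mean
    over the pooled control genes.
    """
    present = [g for g in gene_set if g in expr.index]
    if not present:
        raise ValueError(f"gene set {set_name!r} has no genes in the matrix")
    setset = set(present)
    pool = [g for g in expr.index if g not in setset]
    if not pool:
        raise ValueError(
            f"gene set {set_name!r} covers every gene: no control pool remains"
        )
    avg = expr.mean(axis=1)
    bins = _expression_bins(avg, n_bins)
    rng = np.random.default_rng(seed)
    controls: set[str] = set()
    by_bin: dict[int, list[str]] = {}
    for g in pool:
        by_bin.setdefault(int(bins[g]), []).append(g)
    for g in present:
        candidates = by_bin.get(int(bins[g]), [])
        if not candidates:
            continue
        take = min(n_control, len(candidates))
        chosen = rng.choice(len(candidates), size=take, replace=False)
        controls.update(candidates[i] for i in chosen)
    if not controls:
        raise ValueError(f"gene set {set_name!r}: control bins are exhausted")
    ctrl = sorted(controls)
    scores = expr.loc[present].mean(axis=0) - expr.loc[ctrl].mean(axis=0)
    return ModuleScore(
        scores.rename(set_name), set_name, n_bins, n_control, seed, ctrl
    )


def wave_scores(
    expr: pd.DataFrame,
    wave_gene_sets: dict[str, list[str]],
    n_bins: int = 24,
    n_control: int = 100,
    seed: int = 0,
) -> dict[str, ModuleScore]:
    """Module score per wave gene set (shared binning and seed)."""
    out = {}
    for wave, genes in wave_gene_sets.items():
        if not genes:
            raise ValueError(f"wave {wave!r} has an empty gene set")
        out[wave] = module_score(
            expr, genes, n_bins=n_bins, n_control=n_control, seed=seed, set_name=wave
        )
    return out


def geneset_correlation_matrix(expr: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Pairwise Pearson correlation between the listed genes across samples.

    Zero-variance genes get correlation 0 against everything (flagged via
    the returned frame's ``attrs['zero_variance']``).
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    sub = expr.loc[genes]
    sd = sub.std(axis=1)
    flat = [g for g in genes if sd[g] == 0]
    corr = sub.T.corr(method="pearson")
    for g in flat:
        corr.loc[g, :] = 0.0
        corr.loc[:, g] = 0.0
        corr.loc[g, g] = 1.0
    corr = corr.fillna(0.0)
    corr.attrs["zero_variance"] = flat
    return corr
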
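"""Knockdown-panel analysis: efficiency, effect scores, validated edges, PCA.

Each shRNA perturbation is compared against the scramble (SCR) control.
Knockdown efficiency gates which perturbations are trusted; the effect of a
knockdown on a gene of interest is the double-ratio score

    log10(perturbed GOI / control GOI) - log10(perturbed SCR / control SCR)

where "control" denotes the matched unperturbed-condition expression.
Significant responders to a knockdown become sign-annotated "validated"
regulatory edges with the sign inverted relative to the response (a gene
that rises when its TF is removed is repressed by it). A PCA over the
TF x GOI effect matrix splits the perturbed regulators into two modules by
the sign of their first-component score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SCRAMBLE_LABEL, CountMatrix, SampleDesign
from .de import DEResult, estimate_dispersion, estimate_size_factors, test_wald


@dataclass
class PerturbationQuartet:
    """The four expressions entering one effect score (common normalized
    scale, pseudocounted so all are positive)."""

    perturbed_goi: float
    control_goi: float
    perturbed_scr: float
    control_scr: float

    def __post_init__(self) -> None:
        vals = (self.perturbed_goi, self.control_goi, self.perturbed_scr, self.control_scr)
        if any(v <= 0 for v in vals):
            raise ValueError(f"quartet values must be positive, got {vals}")


@dataclass(frozen=True)
class ValidatedEdge:
    """TF->target edge confirmed by the target's knockdown response."""

    tf: str
    target: str
    sign: str  # "up" | "down"
    fdr: float
    source: str = "perturbation"


@dataclass
class RegulatorModules:
    """PCA summary of the knockdown effect matrix."""

    scores: pd.DataFrame  # TFs x components
    loadings: pd.DataFrame  # genes x components
    variance_explained: pd.Series
    modules: pd.Series  # TF -> "module_1" | "module_2"


def knockdown_efficiency(perturbed_expr: float, scramble_expr: float) -> float:
    """1 - perturbed/scramble, clipped to [0, 1]."""
    if scramble_expr <= 0:
        raise ValueError("scramble expression must be positive")
    return float(np.clip(1.0 - perturbed_expr / scramble_expr, 0.0, 1.0))


def knockdown_effect_score(q: PerturbationQuartet) -> float:
    """Double-ratio score on the log10 scale (0 when the GOI and scramble
    fold changes coincide)."""
    return float(
        np.log10(q.perturbed_goi / q.control_goi)
        - np.log10(q.perturbed_scr / q.control_scr)
    )


def _panel_subset(panel: CountMatrix, labels: set[str], condition: str | None) -> CountMatrix:
    tab = panel.design.table
    pert = tab["perturbation"].map(lambda v: None if v is None or pd.isna(v) else str(v))
    keep = pert.isin(labels)
    if condition is not None:
        keep &= tab["condition"] == condition
    ids = list(tab.index[keep])
    return panel.subset_samples(ids)


def measure_knockdown_efficiencies(
    panel: CountMatrix,
    tfs: list[str],
    condition: str = "treated",
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-TF efficiency from mean size-factor-normalized expression of the
    TF under its own shRNA versus under scramble."""
    sf = estimate_size_factors(panel)
    norm = panel.values.to_numpy(float) / sf.to_numpy(float)[None, :]
    norm = pd.DataFrame(norm, index=panel.gene_ids, columns=panel.values.columns)
    tab = panel.design.table
    pert = tab["perturbation"].map(lambda v: None if v is None or pd.isna(v) else str(v))
    out = {}
    scr_ids = tab.index[(pert == SCRAMBLE_LABEL) & (tab["condition"] == condition)]
    if len(scr_ids) == 0:
        raise ValueError("panel has no scramble (SCR) samples")
    for tf in tfs:
        kd_ids = tab.index[(pert == tf) & (tab["condition"] == condition)]
        if len(kd_ids) == 0:
            raise ValueError(f"panel has no samples for perturbation {tf!r}")
        kd = norm.loc[tf, kd_ids].mean() + pseudocount
        scr = norm.loc[tf, scr_ids].mean() + pseudocount
        out[tf] = knockdown_efficiency(kd, scr)
    return pd.Series(out, name="efficiency")


def effect_score_matrix(
    panel: CountMatrix,
    tfs: list[str],
    genes_of_interest: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """TFs x GOIs matrix of knockdown effect scores.

    For each perturbation label the "perturbed" expression is the treated
    mean and the "control" the untreated mean, each on the common
    size-factor-normalized scale plus a pseudocount.
    """
    missing = [g for g in genes_of_interest if g not in set(panel.gene_ids)]
    if missing:
        raise ValueError(f"genes of interest absent from panel: {missing}")
    sf = estimate_size_factors(panel)
    norm = pd.DataFrame(
        panel.values.to_numpy(float) / sf.to_numpy(float)[None, :],
        index=panel.gene_ids,
        columns=panel.values.columns,
    )
    tab = panel.design.table
    pert = tab["perturbation"].map(lambda v: None if v is None or pd.isna(v) else str(v))

    def mean_expr(label: str, condition: str) -> pd.Series:
        ids = tab.index[(pert == label) & (tab["condition"] == condition)]
        if len(ids) == 0:
            raise ValueError(f"no {condition} samples for perturbation {label!r}")
        return norm.loc[genes_of_interest, ids].mean(axis=1) + pseudocount

    scr_t = mean_expr(SCRAMBLE_LABEL, "treated")
    scr_c = mean_expr(SCRAMBLE_LABEL, "control")
    rows = {}
    for tf in tfs:
        kd_t = mean_expr(tf, "treated")
        kd_c = mean_expr(tf, "control")
        rows[tf] = np.log10(kd_t / kd_c) - np.log10(scr_t / scr_c)
    return pd.DataFrame(rows).T[genes_of_interest]


def perturbation_de(
    panel: CountMatrix,
    tf: str,
    fdr_threshold: float = 0.05,
    condition: str = "treated",
    size_factors: pd.Series | None = None,
    dispersion: pd.Series | None = None,
) -> DEResult:
    """Wald test of a TF's knockdown samples against scramble.

    Runs on one treatment arm of the panel; the scramble samples play the
    role of "control" and the knockdown samples of "treated" in the NB
    regression, so a positive log2FC means up upon knockdown. Size factors
    and dispersions default to panel-wide estimates — the whole panel's
    design cells inform the per-gene dispersion, not just the two cells
    being contrasted.
    """
    tab = panel.design.table
    pert = tab["perturbation"].map(lambda v: None if v is None or pd.isna(v) else str(v))
    if not (pert == SCRAMBLE_LABEL).any():
        raise ValueError("panel has no scramble (SCR) samples")
    if not (pert == tf).any():
        raise ValueError(f"TF {tf!r} absent from panel perturbations")
    if size_factors is None:
        size_factors = estimate_size_factors(panel)
    if dispersion is None:
        dispersion = estimate_dispersion(panel, size_factors=size_factors)
    sub = _panel_subset(panel, {tf, SCRAMBLE_LABEL}, condition)
    relabeled = sub.design.table.copy()
    sub_pert = relabeled["perturbation"].map(
        lambda v: None if v is None or pd.isna(v) else str(v)
    )
    relabeled["condition"] = np.where(sub_pert == tf, "treated", "control")
    cm = CountMatrix(sub.values, SampleDesign(relabeled))
    return test_wald(cm, size_factors.loc[cm.values.columns], dispersion)


def infer_validated_edges(
    de: DEResult, tf: str, fdr_threshold: float = 0.05
) -> list[ValidatedEdge]:
    """Significant knockdown responders become validated edges with the
    inverted sign; the TF's self-edge is excluded."""
    sig = de.table[(de.table["fdr"] < fdr_threshold) & (de.table["log2_fold_change"] != 0)]
    edges = []
    for gene, row in sig.iterrows():
        if gene == tf:
            continue
        sign = "down" if row["log2_fold_change"] > 0 else "up"
        edges.append(ValidatedEdge(tf, str(gene), sign, float(row["fdr"])))
    return edges


def perturbation_pca(effect_matrix: pd.DataFrame, scale: bool = False) -> RegulatorModules:
    """Column-centered SVD of the TF x GOI effect matrix.

    Modules split by the sign of the PC1 score, with the largest-|PC1| TF
    anchoring module_1 (removing the global sign ambiguity of the SVD).
    """
    if effect_matrix.shape[0] < 2 or effect_matrix.shape[1] < 2:
        raise ValueError("need >= 2 TFs and >= 2 genes for PCA")
    if effect_matrix.isna().any().any():
        raise ValueError("effect matrix contains missing values")
    X = effect_matrix.to_numpy(float)
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if S[0] <= 1e-12:
        raise ValueError("effect matrix has zero variance (rank 0 after centering)")
    scores = U * S
    anchor = int(np.argmax(np.abs(scores[:, 0])))
    if scores[anchor, 0] < 0:
        scores[:, 0] *= -1
        Vt[0] *= -1
    n = X.shape[0]
    var = S**2 / max(n - 1, 1)
    var_explained = var / var.sum()
    comp = [f"PC{i + 1}" for i in range(len(S))]
    modules = pd.Series(
        np.where(scores[:, 0] >= 0, "module_1", "module_2"),
        index=effect_matrix.index,
        name="module",
    )
    return RegulatorModules(
        scores=pd.DataFrame(scores, index=effect_matrix.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=effect_matrix.columns, columns=comp),
        variance_explained=pd.Series(var_explained, index=comp, name="variance_explained"),
        modules=modules,
    )
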
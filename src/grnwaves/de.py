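"""Consensus differential expression for the treated-vs-control time course.

Three negative-binomial tests are run per gene — a Wald test on the
condition coefficient, a likelihood-ratio test of the condition term, and a
time-course test of the condition:time interaction — each FDR-adjusted by
Benjamini-Hochberg. A gene is called differentially expressed either when
at least two tests agree ("agree_by_two") or when any single test fires
("any"); the call direction comes from the sign of the fitted log2 fold
change.

Normalization is median-of-ratios; dispersion is a pooled gene-wise
method-of-moments estimate with a small floor, held fixed during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .nbglm import build_design, fit_nb_glm

DISPERSION_FLOOR = 1e-8
LN2 = np.log(2.0)

METHODS = ("wald", "lrt", "timecourse")


@dataclass
class DEResult:
    """Per-gene statistics from one testing method.

    ``table`` is indexed by gene with columns log2_fold_change, p_value,
    fdr and flagged (True where the fit was degenerate or non-convergent
    and the p-value was forced to 1).
    """

    table: pd.DataFrame
    method: str

    def significant(self, fdr_threshold: float = 0.05) -> pd.Series:
        return self.table["fdr"] < fdr_threshold


@dataclass
class ConsensusDEResult:
    """Per-method calls plus the consensus call and direction.

    ``table`` columns: one boolean per method, ``consensus`` (bool) and
    ``direction`` in {up, down, mixed, none}.
    """

    table: pd.DataFrame
    rule: str
    fdr_threshold: float

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["consensus"]])

    def direction_of(self, gene: str) -> str:
        return str(self.table.loc[gene, "direction"])


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Genes with a zero in any sample are excluded from the reference; the
    factor of a sample is the median over remaining genes of its count
    divided by the gene's geometric mean across samples.
    """
    values = counts.values if isinstance(counts, CountMatrix) else counts
    arr = values.to_numpy(float)
    nonzero = (arr > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logs = np.log(arr[nonzero])
    ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(factors, index=values.columns, name="size_factor")


def normalize_log_expression(
    counts: CountMatrix | pd.DataFrame,
    size_factors: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = counts.values if isinstance(counts, CountMatrix) else counts
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    sf = size_factors.loc[values.columns].to_numpy(float)
    return pd.DataFrame(
        np.log2(values.to_numpy(float) / sf[None, :] + pseudocount),
        index=values.index,
        columns=values.columns,
    )


def _design_cells(design: pd.DataFrame) -> pd.Series:
    keys = design[["condition", "time_h"]].copy()
    pert = design["perturbation"]
    keys["perturbation"] = pert.map(lambda v: "" if v is None or pd.isna(v) else str(v))
    return pd.Series(list(map(tuple, keys.to_numpy())), index=design.index)


def estimate_dispersion(
    counts: CountMatrix,
    floor: float = DISPERSION_FLOOR,
    size_factors: pd.Series | None = None,
) -> pd.Series:
    """Gene-wise method-of-moments NB dispersion, pooled over design cells.

    Within each (condition, time, perturbation) cell the moment estimate is
    alpha = (s^2 - mean) / mean^2 on size-factor-normalized counts; cells
    are combined by a (n-1)-weighted average and floored at ``floor``.
    Every cell must hold at least two replicates.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    cells = _design_cells(counts.design.table)
    sizes = cells.groupby(cells).size()
    singles = sizes[sizes < 2]
    if len(singles):
        raise ValueError(f"design cells with a single replicate: {list(singles.index)}")
    norm = counts.values.to_numpy(float) / size_factors.to_numpy(float)[None, :]
    num = np.zeros(counts.n_genes)
    den = np.zeros(counts.n_genes)
    for _, idx in cells.groupby(cells).groups.items():
        j = [counts.values.columns.get_loc(s) for s in idx]
        sub = norm[:, j]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(j) - 1
        # ratio-of-sums pooling: solve sum w(s^2 - m) = alpha * sum w m^2
        num += w * (v - m)
        den += w * m**2
    alpha = np.maximum(np.where(den > 0, num / np.maximum(den, 1e-300), floor), floor)
    return pd.Series(alpha, index=counts.gene_ids, name="dispersion")


def _prepare(counts: CountMatrix, size_factors, dispersion):
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, size_factors=size_factors)
    y = counts.values.to_numpy(float)
    offset = np.log(size_factors.loc[counts.values.columns].to_numpy(float))
    alpha = (
        np.broadcast_to(float(dispersion), (counts.n_genes,))
        if np.isscalar(dispersion)
        else dispersion.loc[counts.gene_ids].to_numpy(float)
    )
    return y, offset, alpha


def _result(genes, lfc, p, flagged, method) -> DEResult:
    p = np.where(flagged, 1.0, np.clip(p, 0.0, 1.0))
    lfc = np.where(flagged, 0.0, lfc)
    table = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "p_value": p,
            "fdr": adjust_fdr(pd.Series(p, index=genes)).to_numpy(),
            "flagged": flagged,
        },
        index=pd.Index(genes, name="gene"),
    )
    return DEResult(table, method)


def test_wald(
    counts: CountMatrix,
    size_factors: pd.Series | None = None,
    dispersion: pd.Series | float | None = None,
) -> DEResult:
    """Wald test on the treated-vs-control coefficient of an NB regression
    with categorical time (time terms dropped if only one time point)."""
    design = counts.design.table
    if set(design["condition"].unique()) != {"control", "treated"}:
        raise ValueError("design must contain both control and treated samples")
    y, offset, alpha = _prepare(counts, size_factors, dispersion)
    X, _, ci = build_design(design, condition=True, time=True)
    fit = fit_nb_glm(y, X, alpha, offset)
    beta = fit.coef[:, ci]
    se = np.sqrt(np.maximum(fit.cov[:, ci, ci], 1e-300))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    flagged = (~fit.converged) | (y.sum(axis=1) == 0)
    return _result(counts.gene_ids, beta / LN2, p, flagged, "wald")


def test_lrt(
    counts: CountMatrix,
    size_factors: pd.Series | None = None,
    dispersion: pd.Series | float | None = None,
) -> DEResult:
    """Likelihood-ratio test of the condition term: deviance difference of
    ~condition + time against ~time, chi-square with 1 df."""
    design = counts.design.table
    y, offset, alpha = _prepare(counts, size_factors, dispersion)
    X_full, _, ci = build_design(design, condition=True, time=True)
    X_red, _, _ = build_design(design, condition=False, time=True)
    full = fit_nb_glm(y, X_full, alpha, offset)
    red = fit_nb_glm(y, X_red, alpha, offset)
    stat = np.maximum(red.deviance - full.deviance, 0.0)
    df = X_full.shape[1] - X_red.shape[1]
    p = stats.chi2.sf(stat, df)
    flagged = (~full.converged) | (~red.converged) | (y.sum(axis=1) == 0)
    return _result(counts.gene_ids, full.coef[:, ci] / LN2, p, flagged, "lrt")


def test_timecourse(
    counts: CountMatrix,
    size_factors: pd.Series | None = None,
    dispersion: pd.Series | float | None = None,
) -> DEResult:
    """Time-course test: LRT of the condition:time interaction, detecting
    condition-dependent temporal profiles."""
    design = counts.design.table
    for cond in ("control", "treated"):
        times = design.loc[design["condition"] == cond, "time_h"].unique()
        if len(times) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 time points")
    y, offset, alpha = _prepare(counts, size_factors, dispersion)
    X_full, _, ci = build_design(design, condition=True, time=True, interaction=True)
    X_red, _, _ = build_design(design, condition=True, time=True)
    full = fit_nb_glm(y, X_full, alpha, offset)
    red = fit_nb_glm(y, X_red, alpha, offset)
    stat = np.maximum(red.deviance - full.deviance, 0.0)
    df = X_full.shape[1] - X_red.shape[1]
    p = stats.chi2.sf(stat, df)
    flagged = (~full.converged) | (~red.converged) | (y.sum(axis=1) == 0)
    return _result(counts.gene_ids, red.coef[:, ci] / LN2, p, flagged, "timecourse")


def adjust_fdr(p_values: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.Series(fdr, index=p_values.index, name="fdr")


def consensus_call(
    results: dict[str, DEResult],
    rule: str = "agree_by_two",
    fdr_threshold: float = 0.05,
) -> ConsensusDEResult:
    """Combine the three per-method calls into a consensus.

    ``agree_by_two`` requires at least two methods below the FDR threshold,
    ``any`` at least one. Direction follows the Wald log2 fold change; if
    the calling methods disagree in sign the gene is marked "mixed", and a
    fold change of exactly zero yields "none" (excluded from signed node
    annotation downstream).
    """
    missing = [m for m in METHODS if m not in results]
    if missing:
        raise ValueError(f"missing methods: {missing}")
    if rule not in ("agree_by_two", "any"):
        raise ValueError(f"unknown rule: {rule}")
    genes = results["wald"].table.index
    calls = pd.DataFrame(
        {m: results[m].significant(fdr_threshold).reindex(genes) for m in METHODS},
        index=genes,
    )
    n_calls = calls.sum(axis=1)
    consensus = n_calls >= (2 if rule == "agree_by_two" else 1)
    lfc = pd.DataFrame(
        {m: results[m].table["log2_fold_change"].reindex(genes) for m in METHODS}
    )
    wald_sign = np.sign(lfc["wald"])
    direction = []
    for g in genes:
        calling = [m for m in METHODS if calls.loc[g, m]]
        signs = {int(np.sign(lfc.loc[g, m])) for m in calling} if calling else set()
        s = int(wald_sign.loc[g])
        if len(signs) > 1:
            direction.append("mixed")
        elif s > 0:
            direction.append("up")
        elif s < 0:
            direction.append("down")
        else:
            direction.append("none")
    table = calls.copy()
    table["consensus"] = consensus
    table["direction"] = direction
    return ConsensusDEResult(table, rule, fdr_threshold)


def run_consensus_de(
    counts: CountMatrix,
    rule: str = "agree_by_two",
    fdr_threshold: float = 0.05,
    with_timecourse: bool = True,
) -> tuple[dict[str, DEResult], ConsensusDEResult]:
    """Convenience driver: size factors, dispersion, the three tests and the
    consensus call in one sweep. When the design cannot support the
    interaction test (fewer than two time points per arm) the time-course
    result falls back to the LRT so the consensus stays three-way."""
    sf = estimate_size_factors(counts)
    disp = estimate_dispersion(counts, size_factors=sf)
    results = {
        "wald": test_wald(counts, sf, disp),
        "lrt": test_lrt(counts, sf, disp),
    }
    if with_timecourse:
        results["timecourse"] = test_timecourse(counts, sf, disp)
    else:
        tc = DEResult(results["lrt"].table.copy(), "timecourse")
        results["timecourse"] = tc
    return results, consensus_call(results, rule, fdr_threshold)
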
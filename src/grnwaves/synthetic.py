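"""Synthetic ground truth for the wave-network pipeline.

This module generates everything the downstream analysis consumes, with a
known answer key: a signed TF->target network whose TFs are active in one of
three temporal waves, negative-binomial time-course counts for a two-arm
(control vs cytokine-treated) design, an shRNA knockdown panel with a
scramble control, and dense log-expression matrices for gene-set scoring.

The treated arm follows a pulse model on the log2 scale: each TF's activity
is a log-normal-shaped pulse of unit peak height centred in its wave window
(early 1-2 h, intermediate 4-16 h, late 48-96 h), and each target's log2
mean is its flat baseline plus ``sign * effect * activity`` summed over its
incoming edges. Control samples stay at baseline throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SCRAMBLE_LABEL, CountMatrix, SampleDesign

WAVE_LABELS = ("early", "intermediate", "late")

#: Post-treatment window (hours) in which each wave's TFs peak.
WAVE_WINDOWS: dict[str, tuple[float, float]] = {
    "early": (1.0, 2.0),
    "intermediate": (4.0, 16.0),
    "late": (48.0, 96.0),
}

#: Ten-point sampling grid covering 0-96 h and every wave window.
DEFAULT_TIME_GRID = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0, 48.0, 72.0, 96.0)


@dataclass
class GroundTruthNetwork:
    """Signed bipartite TF->target network with per-TF wave labels."""

    tfs: list[str]
    targets: list[str]
    edges: list[tuple[str, str, int, float]]  # (tf, target, sign, effect)
    wave_of_tf: dict[str, str]

    def __post_init__(self) -> None:
        tfset, tgset = set(self.tfs), set(self.targets)
        seen: set[tuple[str, str]] = set()
        for tf, target, sign, effect in self.edges:
            if tf not in tfset or target not in tgset:
                raise ValueError(f"edge ({tf}, {target}) has unknown endpoint")
            if (tf, target) in seen:
                raise ValueError(f"duplicate edge ({tf}, {target})")
            seen.add((tf, target))
            if sign not in (1, -1):
                raise ValueError(f"edge sign must be +1/-1, got {sign}")
            if effect <= 0:
                raise ValueError(f"edge effect must be positive, got {effect}")
        bad = set(self.wave_of_tf) - tfset
        if bad:
            raise ValueError(f"wave labels for unknown TFs: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return self.tfs + self.targets

    def edge_signs(self) -> dict[tuple[str, str], int]:
        return {(tf, tg): s for tf, tg, s, _ in self.edges}

    def incoming(self) -> dict[str, list[tuple[str, int, float]]]:
        inc: dict[str, list[tuple[str, int, float]]] = {}
        for tf, tg, s, e in self.edges:
            inc.setdefault(tg, []).append((tf, s, e))
        return inc

    def to_tsv(self, path) -> None:
        """Write the edge list as TSV (tf, target, sign, effect)."""
        df = pd.DataFrame(self.edges, columns=["tf", "target", "sign", "effect"])
        df.to_csv(path, sep="\t", index=False)


@dataclass
class SimulationParams:
    """Knobs for the count simulator.

    time_grid is in hours and must start at 0 (the untreated baseline);
    dispersion is the negative-binomial alpha in Var = mu + alpha*mu^2;
    library sizes are drawn log-uniformly from ``library_size_range``;
    ``tf_log2_amplitude`` is the peak log2 induction of an active TF and
    ``pulse_log_sd`` the pulse width in log-time.
    """

    time_grid: tuple[float, ...] = DEFAULT_TIME_GRID
    n_replicates: int = 3
    library_size_range: tuple[float, float] = (0.7, 1.4)
    dispersion: float = 0.1
    baseline_mean_range: tuple[float, float] = (20.0, 2000.0)
    knockdown_efficiency: float = 0.9
    tf_log2_amplitude: float = 3.0
    pulse_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.time_grid)
        if len(grid) == 0:
            raise ValueError("time grid is empty")
        if grid[0] != 0.0:
            raise ValueError("time grid must begin at 0 (baseline)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("time grid must be strictly increasing")
        self.time_grid = grid
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if not (0.0 <= self.knockdown_efficiency <= 1.0):
            raise ValueError("knockdown_efficiency must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")


def wave_peak_time(wave: str) -> float:
    """Geometric-mean centre of a wave window."""
    lo, hi = WAVE_WINDOWS[wave]
    return math.sqrt(lo * hi)


def pulse_activity(t: float, wave: str, log_sd: float = 0.5) -> float:
    """Unit-peak log-normal-shaped activity of a wave's TFs at time t.

    Zero at baseline (t = 0) and for flat TFs (wave not in the three
    windows); elsewhere a Gaussian in log-time centred at the window's
    geometric mean.
    """
    if t <= 0 or wave not in WAVE_WINDOWS:
        return 0.0
    z = (math.log(t) - math.log(wave_peak_time(wave))) / log_sd
    return math.exp(-0.5 * z * z)


def generate_ground_truth_network(
    n_tfs: int,
    n_targets: int,
    edge_density: float,
    repressor_fraction: float = 0.0,
    seed: int = 0,
    effect_range: tuple[float, float] = (1.5, 2.5),
) -> GroundTruthNetwork:
    """Random bipartite TF->target network.

    Each of the n_tfs * n_targets possible edges is kept independently with
    probability ``edge_density``; kept edges are repressive (sign -1) with
    probability ``repressor_fraction`` and carry a log2 effect size drawn
    uniformly from ``effect_range``. TFs get a wave label uniformly from
    {early, intermediate, late}.
    """
    if n_tfs < 1 or n_targets < 1:
        raise ValueError("n_tfs and n_targets must be >= 1")
    if not (0.0 < edge_density <= 1.0):
        raise ValueError("edge_density must lie in (0, 1]")
    if not (0.0 <= repressor_fraction <= 1.0):
        raise ValueError("repressor_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i:03d}" for i in range(n_tfs)]
    targets = [f"G{i:05d}" for i in range(n_targets)]
    keep = rng.random((n_tfs, n_targets)) < edge_density
    is_rep = rng.random((n_tfs, n_targets)) < repressor_fraction
    lo, hi = effect_range
    effects = rng.uniform(lo, hi, size=(n_tfs, n_targets))
    edges = [
        (tfs[i], targets[j], -1 if is_rep[i, j] else 1, float(effects[i, j]))
        for i in range(n_tfs)
        for j in range(n_targets)
        if keep[i, j]
    ]
    waves = rng.choice(WAVE_LABELS, size=n_tfs)
    wave_of_tf = {tf: str(w) for tf, w in zip(tfs, waves)}
    return GroundTruthNetwork(tfs, targets, edges, wave_of_tf)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial draw with Var = mu + alpha*mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean)
    return rng.poisson(lam)


def expected_log2_means(
    network: GroundTruthNetwork, params: SimulationParams, baselines: pd.Series
) -> pd.DataFrame:
    """Analytic per-gene log2 mean for every (condition, time) cell.

    Columns are a MultiIndex (condition, time_h). ``baselines`` holds each
    gene's flat log2 baseline (as produced by :func:`simulate_time_course`,
    which exposes the ones it drew).
    """
    incoming = network.incoming()
    cols = pd.MultiIndex.from_tuples(
        [(c, t) for c in ("control", "treated") for t in params.time_grid],
        names=["condition", "time_h"],
    )
    out = pd.DataFrame(
        np.tile(baselines.values[:, None], (1, len(cols))),
        index=baselines.index,
        columns=cols,
    )
    for t in params.time_grid:
        act = {
            w: pulse_activity(t, w, params.pulse_log_sd)
            for w in set(network.wave_of_tf.values())
        }
        for tf in network.tfs:
            a = act.get(network.wave_of_tf.get(tf, "flat"), 0.0)
            out.loc[tf, ("treated", t)] += params.tf_log2_amplitude * a
        for tg, inc in incoming.items():
            shift = sum(
                s * e * act.get(network.wave_of_tf.get(tf, "flat"), 0.0)
                for tf, s, e in inc
            )
            out.loc[tg, ("treated", t)] += shift
    return out


def _draw_baselines(
    rng: np.random.Generator, genes: list[str], params: SimulationParams
) -> pd.Series:
    lo, hi = params.baseline_mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    return pd.Series(np.log2(means), index=genes, name="log2_baseline")


def simulate_time_course(
    network: GroundTruthNetwork, params: SimulationParams
) -> tuple[CountMatrix, pd.Series]:
    """Simulate the two-condition time course.

    Returns the count matrix (one sample per condition x time x replicate)
    together with the per-gene log2 baselines actually drawn, so tests can
    reconstruct the analytic means via :func:`expected_log2_means`.
    """
    rng = np.random.default_rng(params.seed)
    genes = network.genes
    baselines = _draw_baselines(rng, genes, params)
    log2_means = expected_log2_means(network, params, baselines)

    sample_rows = []
    mean_cols = []
    for cond in ("control", "treated"):
        for t in params.time_grid:
            for r in range(1, params.n_replicates + 1):
                sid = f"{cond}_t{t:g}_r{r}"
                sample_rows.append((sid, cond, t, f"r{r}", None))
                mean_cols.append((cond, t))
    lo, hi = params.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(sample_rows)))

    base = np.power(2.0, log2_means[mean_cols].values)  # genes x samples
    mu = base * lib[None, :]
    counts = _nb_draw(rng, mu, params.dispersion)

    design = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "condition", "time_h", "replicate", "perturbation"],
    ).set_index("sample_id")
    values = pd.DataFrame(counts, index=genes, columns=design.index)
    return CountMatrix(values, SampleDesign(design)), baselines


def simulate_perturbation_panel(
    network: GroundTruthNetwork,
    perturbed_tfs: list[str],
    params: SimulationParams,
) -> CountMatrix:
    """Simulate the endpoint shRNA knockdown panel.

    For each perturbed TF and for the scramble control, ``n_replicates``
    samples are drawn in each condition at the final time point. The panel
    models a steady endpoint at which every non-flat TF is fully active
    under treatment: knocking a TF down multiplies its own mean by
    ``1 - knockdown_efficiency`` in both conditions and scales its treated
    regulatory input to each target by the same factor.
    """
    unknown = [tf for tf in perturbed_tfs if tf not in set(network.tfs)]
    if unknown:
        raise ValueError(f"perturbed TFs not in network: {unknown}")
    rng = np.random.default_rng(params.seed)
    genes = network.genes
    baselines = _draw_baselines(rng, genes, params)
    incoming = network.incoming()
    eff = params.knockdown_efficiency
    t_end = params.time_grid[-1]

    def is_active(tf: str) -> bool:
        return network.wave_of_tf.get(tf, "flat") in WAVE_WINDOWS

    labels = list(perturbed_tfs) + [SCRAMBLE_LABEL]
    sample_rows = []
    mean_cols = []
    gene_index = {g: i for i, g in enumerate(genes)}
    # one analytic log2-mean column per (label, condition)
    mean_mat = {}
    for label in labels:
        for cond in ("control", "treated"):
            col = baselines.values.copy()
            for tf in network.tfs:
                i = gene_index[tf]
                if cond == "treated" and is_active(tf):
                    col[i] += params.tf_log2_amplitude
                if tf == label:
                    # knockdown scales the TF's own mean by (1 - efficiency)
                    col[i] += np.log2(max(1.0 - eff, 1e-12))
            if cond == "treated":
                for tg, inc in incoming.items():
                    i = gene_index[tg]
                    shift = 0.0
                    for tf, s, e in inc:
                        act = 1.0 if is_active(tf) else 0.0
                        if tf == label:
                            act *= 1.0 - eff
                        shift += s * e * act
                    col[i] += shift
            mean_mat[(label, cond)] = col
            for r in range(1, params.n_replicates + 1):
                sid = f"{label}_{cond}_r{r}"
                sample_rows.append((sid, cond, t_end, f"r{r}", label))
                mean_cols.append((label, cond))

    lo, hi = params.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(sample_rows)))
    base = np.power(2.0, np.stack([mean_mat[c] for c in mean_cols], axis=1))
    counts = _nb_draw(rng, base * lib[None, :], params.dispersion)
    design = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "condition", "time_h", "replicate", "perturbation"],
    ).set_index("sample_id")
    values = pd.DataFrame(counts, index=genes, columns=design.index)
    return CountMatrix(values, SampleDesign(design))


def simulate_score_matrix(
    gene_sets: dict[str, list[str]],
    n_samples: int,
    shift: float,
    seed: int = 0,
    n_background: int = 300,
    shifted_fraction: float = 0.5,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.Index]:
    """Dense log-expression fixture for module scoring.

    Genes are the union of the sets plus ``n_background`` unrelated genes;
    expression is gene baseline + Gaussian noise, with all set genes shifted
    by ``shift`` in a designated block of samples (the last
    ``shifted_fraction`` of them). Returns the genes x samples matrix and
    the shifted sample ids.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not gene_sets or all(len(v) == 0 for v in gene_sets.values()):
        raise ValueError("gene sets are empty")
    set_genes = sorted({g for genes in gene_sets.values() for g in genes})
    genes = set_genes + [f"BG{i:05d}" for i in range(n_background)]
    rng = np.random.default_rng(seed)
    base = rng.uniform(2.0, 8.0, size=len(genes))
    expr = base[:, None] + rng.normal(0.0, noise_sd, size=(len(genes), n_samples))
    samples = [f"S{i:04d}" for i in range(n_samples)]
    n_shift = int(round(shifted_fraction * n_samples))
    shifted = pd.Index(samples[n_samples - n_shift :])
    df = pd.DataFrame(expr, index=genes, columns=samples)
    if n_shift:
        df.loc[set_genes, shifted] += shift
    return df, shifted


def demo_ground_truth(
    seed: int = 0,
    n_tfs_per_wave: int = 8,
    n_flat_tfs: int = 4,
    n_targets: int = 1200,
    hub_out_degree: int = 60,
    tf_out_degree: int = 12,
    repressor_fraction: float = 0.2,
    effect_range: tuple[float, float] = (1.5, 2.5),
) -> GroundTruthNetwork:
    """Bundled demo network: three waves of TFs plus one hub per wave.

    Every wave holds ``n_tfs_per_wave`` TFs; the first TF of each wave is a
    hub with ``hub_out_degree`` targets (the rest get ``tf_out_degree``),
    making it the dominant regulator of its wave by construction. Flat TFs
    and unconnected targets provide the non-responding background.
    """
    rng = np.random.default_rng(seed)
    tfs: list[str] = []
    wave_of_tf: dict[str, str] = {}
    for w in WAVE_LABELS:
        for i in range(n_tfs_per_wave):
            name = f"TF_{w.upper()}_{i:02d}"
            tfs.append(name)
            wave_of_tf[name] = w
    for i in range(n_flat_tfs):
        name = f"TF_FLAT_{i:02d}"
        tfs.append(name)
        wave_of_tf[name] = "flat"
    targets = [f"G{i:05d}" for i in range(n_targets)]
    lo, hi = effect_range
    edges: list[tuple[str, str, int, float]] = []
    for tf in tfs:
        if wave_of_tf[tf] == "flat":
            continue
        k = hub_out_degree if tf.endswith("_00") else tf_out_degree
        chosen = rng.choice(n_targets, size=min(k, n_targets), replace=False)
        for j in sorted(chosen):
            sign = -1 if rng.random() < repressor_fraction else 1
            edges.append((tf, targets[j], sign, float(rng.uniform(lo, hi))))
    # deduplicate (tf, target) collisions cannot occur: one draw per tf
    return GroundTruthNetwork(tfs, targets, edges, wave_of_tf)
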
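import numpy as np
import pandas as pd
import pytest

from grnwaves.containers import CountMatrix, SampleDesign


def make_design(
    conditions, times, n_reps, perturbation=None
) -> pd.DataFrame:
    rows = []
    for cond in conditions:
        for t in times:
            for r in range(1, n_reps + 1):
                sid = f"{cond}_t{t:g}_r{r}"
                rows.append((sid, cond, float(t), f"r{r}", perturbation))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "time_h", "replicate", "perturbation"]
    ).set_index("sample_id")


def nb_counts(rng, mu, alpha):
    """Gamma-Poisson draw with Var = mu + alpha*mu^2."""
    mu = np.asarray(mu, float)
    if alpha <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / alpha, alpha * mu)
    return rng.poisson(lam)


def count_matrix_from_mu(rng, mu, design, alpha=0.1, genes=None) -> CountMatrix:
    y = nb_counts(rng, mu, alpha)
    genes = genes or [f"g{i}" for i in range(mu.shape[0])]
    return CountMatrix(
        pd.DataFrame(y, index=genes, columns=design.index), SampleDesign(design)
    )


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the bundled synthetic fixture, shared by
    the tests that inspect its artifacts."""
    from grnwaves.pipeline import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("demo") / "run"
    cfg = PipelineConfig(outdir=str(outdir), seed=11, synthetic={})
    manifest = run_pipeline(cfg)
    return cfg, manifest, outdir
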
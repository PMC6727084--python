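import numpy as np
import pytest

from fuseaft import CancerDataset, calibrate_censoring, compute_km_weights


def make_cohorts(K=3, p=6, n=60, seed=0, beta=None, censor=0.2, dist="normal"):
    """Simulated canonical cohorts with KM weights, for solver tests.

    ``beta`` may be a (p,) vector shared across cohorts or a (p, K) matrix.
    """
    rng = np.random.default_rng(seed)
    if beta is None:
        beta = np.zeros(p)
        beta[: min(2, p)] = 1.2
    beta = np.asarray(beta, dtype=float)
    if beta.ndim == 1:
        beta = np.tile(beta[:, None], (1, K))
    genes = [f"G{j + 1}" for j in range(p)]
    dsets = []
    for k in range(K):
        if dist == "normal":
            X = rng.standard_normal((n, p))
        else:
            Z = rng.standard_normal((n, p))
            X = (Z + 0.3 * (Z**2 - 1.0)) / np.sqrt(1.18)
        logT = X @ beta[:, k] + rng.standard_normal(n)
        cens = calibrate_censoring(logT, censor, rng)
        dsets.append(
            CancerDataset.from_log_times(f"C{k + 1}", genes, X, cens.y, cens.delta)
        )
    weights = [compute_km_weights(ds) for ds in dsets]
    return dsets, weights


@pytest.fixture
def small_cohorts():
    return make_cohorts(K=3, p=6, n=60, seed=42)


@pytest.fixture
def toy_tables(tmp_path):
    """cBioPortal-style genes x samples expression + clinical TSVs."""
    expr = tmp_path / "expr.tsv"
    expr.write_text(
        "Hugo_Symbol\tS1\tS2\tS3\tS4\n"
        "TP53\t1.0\t2.0\t3.0\t4.0\n"
        "EGFR\t0.5\t0.1\t0.9\t0.3\n"
        "KRAS\t2.5\t2.1\t1.9\t2.3\n"
    )
    clin = tmp_path / "clin.tsv"
    clin.write_text(
        "SAMPLE_ID\tOS_MONTHS\tOS_STATUS\n"
        "S1\t12.5\tDECEASED\n"
        "S2\t30.0\tLIVING\n"
        "S3\t5.2\tDECEASED\n"
        "S4\t48.1\tLIVING\n"
    )
    return expr, clin
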
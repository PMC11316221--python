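import numpy as np
import pytest

from rebar import AssayDesign, CountDataset, LogCountMatrix
from rebar.fitting import residual_projector


def _logc_from_values(values, timepoints_per_assay, observed=None):
    """Wrap a raw (variants x samples) array as a normalized LogCountMatrix."""
    values = np.asarray(values, dtype=float)
    assays = []
    col = 0
    for j, tps in enumerate(timepoints_per_assay):
        tps = tuple(float(t) for t in tps)
        assays.append(
            AssayDesign(
                assay_id=f"A{j + 1}",
                timepoints=tps,
                sample_ids=tuple(f"A{j + 1}_t{k}" for k in range(len(tps))),
            )
        )
        col += len(tps)
    variant_ids = tuple(f"v{i:03d}" for i in range(values.shape[0]))
    return LogCountMatrix(variant_ids, tuple(assays), values, "normalized", observed)


def _noiseless_rank_one(
    n_variants=40,
    n_controls=8,
    n_assays=3,
    timepoints=(0.0, 1.0, 2.0, 3.0),
    seed=0,
    sigma_f=0.1,
    sigma_u=1.0,
    sigma_lambda=0.05,
    sigma_gamma=0.05,
):
    """Exactly rank-one-biased log-linear data with known truth.

    Control variants (the first n_controls) share identical true fitness 0;
    gamma is orthogonal to {1, t} within each assay, so the pre-correction
    identity slope = f + u*lambda holds exactly.
    """
    rng = np.random.default_rng(seed)
    f = rng.normal(0.0, sigma_f, n_variants)
    f[:n_controls] = 0.0
    c = rng.normal(0.0, 1.0, n_variants)
    u = rng.normal(0.0, sigma_u, n_variants)
    lam = rng.normal(0.0, sigma_lambda, n_assays)
    t = np.asarray(timepoints, dtype=float)
    P = residual_projector(t)
    cols = []
    gammas = []
    for a in range(n_assays):
        g = P @ rng.normal(0.0, sigma_gamma, t.size)
        gammas.append(g)
        v = lam[a] * t + g
        cols.append(c[:, None] + np.outer(f, t) + np.outer(u, v))
    values = np.hstack(cols)
    logc = _logc_from_values(values, [timepoints] * n_assays)
    truth = {
        "f": f,
        "c": c,
        "u": u,
        "lam": lam,
        "gamma": np.concatenate(gammas),
        "control_ids": logc.variant_ids[:n_controls],
    }
    return logc, truth


def _toy_dataset(seed=0, n_variants=5, timepoints=(0.0, 1.0, 2.0, 3.0), n_assays=1):
    rng = np.random.default_rng(seed)
    assays = tuple(
        AssayDesign(
            assay_id=f"A{j + 1}",
            timepoints=timepoints,
            sample_ids=tuple(f"A{j + 1}_t{k}" for k in range(len(timepoints))),
        )
        for j in range(n_assays)
    )
    n_samples = n_assays * len(timepoints)
    counts = rng.integers(1, 500, size=(n_variants, n_samples))
    return CountDataset(
        variant_ids=tuple(f"v{i:03d}" for i in range(n_variants)),
        assays=assays,
        counts=counts,
        depths=counts.sum(axis=0).astype(float),
    )


@pytest.fixture
def logc_from_values():
    return _logc_from_values


@pytest.fixture
def noiseless_rank_one():
    return _noiseless_rank_one


@pytest.fixture
def toy_dataset():
    return _toy_dataset
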
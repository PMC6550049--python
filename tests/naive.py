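"""Independent straightforward reference implementations used as oracles.

These deliberately re-code the resampling loops and distance geometry
with plain per-resample Python loops and explicit double loops, sharing
only numpy's elementary reductions (mean/var/quantile) with the package.
They follow the same documented randomness contract: one default_rng
per call, all group-A indices drawn as a single ``integers`` call of
shape (n_boot, n_a), then group-B.
"""
import math

import numpy as np


def naive_distance_vector(coords):
    """All unique pairwise distances by explicit double loop."""
    k = len(coords)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            out.append(
                math.sqrt(
                    (coords[i][0] - coords[j][0]) ** 2
                    + (coords[i][1] - coords[j][1]) ** 2
                    + (coords[i][2] - coords[j][2]) ** 2
                )
            )
    return np.array(out)


def naive_rows(dataset):
    return np.stack(
        [naive_distance_vector(c.coordinates) for c in dataset.configurations]
    )


def naive_mean_form(rows, estimator):
    if estimator == "arithmetic":
        return rows.mean(axis=0)
    mean_d = rows.mean(axis=0)
    corrected = (rows ** 2).mean(axis=0) - rows.var(axis=0, ddof=1)
    return np.where(corrected <= 0.0, mean_d,
                    np.sqrt(np.where(corrected <= 0.0, 1.0, corrected)))


def naive_bootstrap_ci(group_a, group_b, n_boot, confidence_level, seed,
                       estimator="arithmetic"):
    """Per-resample loop version of the FDM percentile bootstrap."""
    rows_a, rows_b = naive_rows(group_a), naive_rows(group_b)
    n_a, n_b = len(rows_a), len(rows_b)
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, n_a, size=(n_boot, n_a))
    idx_b = rng.integers(0, n_b, size=(n_boot, n_b))
    boot = []
    for b in range(n_boot):
        ma = naive_mean_form(rows_a[idx_a[b]], estimator)
        mb = naive_mean_form(rows_b[idx_b[b]], estimator)
        boot.append(ma / mb)
    boot = np.stack(boot)
    alpha = 1.0 - confidence_level
    lower = np.quantile(boot, alpha / 2.0, axis=0)
    upper = np.quantile(boot, 1.0 - alpha / 2.0, axis=0)
    return lower, upper


def naive_form_test(group_a, group_b, n_boot, seed, estimator="arithmetic"):
    """Per-resample loop version of the pooled mean-form test."""
    rows_a, rows_b = naive_rows(group_a), naive_rows(group_b)
    n_a, n_b = len(rows_a), len(rows_b)
    ratios = naive_mean_form(rows_a, estimator) / naive_mean_form(rows_b, estimator)
    t_obs = ratios.max() / ratios.min()
    pool = np.concatenate([rows_a, rows_b])
    rng = np.random.default_rng(seed)
    idx_a = rng.integers(0, n_a + n_b, size=(n_boot, n_a))
    idx_b = rng.integers(0, n_a + n_b, size=(n_boot, n_b))
    exceed = 0
    t_null = []
    for b in range(n_boot):
        r = naive_mean_form(pool[idx_a[b]], estimator) / \
            naive_mean_form(pool[idx_b[b]], estimator)
        t = r.max() / r.min()
        t_null.append(t)
        if t >= t_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_boot)
    return t_obs, np.array(t_null), p


def random_rigid_transform(rng, reflect=False):
    """A uniformly random rotation (optionally a reflection) + translation."""
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if reflect != (np.linalg.det(q) < 0):
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-10.0, 10.0, size=3)
    return q, t
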
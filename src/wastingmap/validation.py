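"""De-clustered hold-out splitting and predictive-performance indices.

Survey clusters are strongly clumped in space and repeat over year-seasons,
so a simple random 10% hold-out would leave near-duplicate neighbours in
the training set.  The split here stratifies observations by
(year-season) x spatial block (k-means on coordinates) and samples
proportionally from every non-empty stratum, so the test set is spread over
space and time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ValidationReport:
    """The four predictive indices on a hold-out set.

    Errors are predicted - observed; rmse = sqrt(mean(err^2)), mean_error =
    mean(err), mean_absolute_error = mean(|err|), correlation = Pearson r
    (None, with ``correlation_defined`` False, when either vector is
    constant).
    """

    rmse: float
    mean_error: float
    mean_absolute_error: float
    correlation: float | None
    correlation_defined: bool
    n_test: int
    split_metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mean_error": self.mean_error,
            "mean_absolute_error": self.mean_absolute_error,
            "correlation": self.correlation,
            "correlation_defined": self.correlation_defined,
            "n_test": self.n_test,
            "split_metadata": self.split_metadata,
        }


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to weights, summing exactly to total."""
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def spatiotemporal_holdout(
    observations: pd.DataFrame, fraction: float = 0.10, seed: int = 0
):
    """Split cluster records into (train, test) de-clustered over space-time.

    Strata are (year, season) x spatial k-means block with
    k = ceil(1/fraction); the test set of size round(fraction * N) is drawn
    proportionally from non-empty strata (largest-remainder allocation), so
    every year-season with enough records contributes test points.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(observations)
    if n < 10:
        raise ValueError("need at least 10 observations to split")
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(seed)
    coords = observations[["x_km", "y_km"]].to_numpy(dtype=float)
    k = min(math.ceil(1.0 / fraction), len(np.unique(coords, axis=0)))
    blocks = KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(coords)

    keys = pd.DataFrame(
        {
            "year": observations["year"].to_numpy(),
            "season": observations["season"].to_numpy(),
            "block": blocks,
        }
    )
    strata_ids, strata = pd.factorize(
        keys.apply(lambda r: (r["year"], r["season"], r["block"]), axis=1)
    )
    counts = np.bincount(strata_ids)
    n_test = int(round(fraction * n))
    alloc = _largest_remainder(counts.astype(float), n_test)
    alloc = np.minimum(alloc, counts)
    # if capping left a shortfall, top up from strata with spare capacity
    while alloc.sum() < n_test:
        spare = np.flatnonzero(counts - alloc > 0)
        alloc[spare[np.argmax((counts - alloc)[spare])]] += 1

    test_idx: list = []
    positions = np.arange(n)
    for s in range(len(counts)):
        members = positions[strata_ids == s]
        if alloc[s]:
            test_idx.extend(rng.choice(members, size=alloc[s], replace=False))
    test_mask = np.zeros(n, dtype=bool)
    test_mask[np.array(test_idx, dtype=int)] = True

    train = observations.loc[~test_mask].copy()
    test = observations.loc[test_mask].copy()
    meta = {
        "seed": seed,
        "fraction": fraction,
        "n_strata": int(len(counts)),
        "n_spatial_blocks": int(k),
        "scheme": "stratified (year-season x k-means spatial block)",
    }
    train.attrs["split"] = test.attrs["split"] = meta
    return train, test


def validation_metrics(
    observed_proportions, predicted_proportions, split_metadata: dict | None = None
) -> ValidationReport:
    """Compute RMSE, mean error, mean absolute error and Pearson correlation."""
    obs = np.asarray(observed_proportions, dtype=float)
    pred = np.asarray(predicted_proportions, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("need equal-length, nonempty vectors")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    me = float(np.mean(err))
    mae = float(np.mean(np.abs(err)))
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        corr, defined = None, False
    else:
        corr = float(np.corrcoef(obs, pred)[0, 1])
        defined = True
    return ValidationReport(
        rmse=rmse,
        mean_error=me,
        mean_absolute_error=mae,
        correlation=corr,
        correlation_defined=defined,
        n_test=obs.size,
        split_metadata=split_metadata or {},
    )
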
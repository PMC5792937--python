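"""Phylogenetically controlled null-model significance test for SDMs.

AUC alone can suggest good performance even for models built on very few
records, so each observed model is compared against a null distribution
of AUCs from models fitted to random draws of localities.  The draws
come from a target-group background pool — the unique collection
localities of a broader reference clade sharing the focal species'
collecting effort and bias — so that a "significant" model must beat
what sampling artefacts alone can achieve.

For each species, R replicate models are fitted to random subsets of
the pool of the same size as the observed locality set, their AUCs are
sorted ascending, and the ceil(0.95 R)-th order statistic (the 95th
element when R = 100, no interpolation) estimates the 95th percentile.
The observed model is significant only when its AUC is strictly greater
than that threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .geodata import EnvStack, OccurrenceSet
from .maxent_sdm import FeatureMatrix, fit_and_score

logger = logging.getLogger(__name__)


@dataclass
class BackgroundPool:
    """Unique localities (feature-matrix rows) of the reference clade.

    ``rows`` indexes the valid-cell rows of a FeatureMatrix; duplicates
    are removed on construction and cells outside the valid domain must
    be rejected by the caller that maps localities to rows.
    """

    rows: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        rows = np.unique(np.asarray(self.rows, dtype=int))
        if rows.size == 0:
            raise DataError("empty background pool")
        if rows.min() < 0:
            raise DataError("negative cell row in background pool")
        self.rows = rows

    def __len__(self) -> int:
        return len(self.rows)


def pool_from_occurrences(occ: OccurrenceSet, features: FeatureMatrix,
                          provenance: str = "target-group occurrences"
                          ) -> BackgroundPool:
    """Build a pool from the unique cells of a (cell-assigned) occurrence
    set; records on masked cells are rejected at construction."""
    if not occ.has_cells:
        raise DataError("pool construction requires cell-assigned records")
    cells = occ.records[["row", "col"]].drop_duplicates().to_numpy(dtype=int)
    rows = features.rows_for_cells(cells)
    return BackgroundPool(rows, provenance=provenance)


@dataclass
class NullModelResult:
    """Observed AUC against its null distribution."""

    observed_auc: float
    replicate_aucs: np.ndarray  # ascending
    threshold: float
    significant: bool
    seed: int | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_aucs)


def null_auc_distribution(pool: BackgroundPool, n: int, features: FeatureMatrix,
                          R: int = 100, reg_multiplier: float = 1.0,
                          max_iterations: int = 500, tolerance: float = 1e-5,
                          seed: int | None = None,
                          background_rows: np.ndarray | None = None
                          ) -> np.ndarray:
    """AUCs of R replicate models fitted to random draws from the pool.

    Each replicate draws n localities without replacement (independently
    across replicates) and is fitted and scored exactly like the
    observed model: same features, regularisation and background.
    Returns the AUCs sorted ascending.
    """
    if n > len(pool):
        raise DataError(f"cannot draw {n} localities from a pool of {len(pool)}")
    if n < 1 or R < 1:
        raise DataError("n and R must be positive")
    rng = np.random.default_rng(seed)
    aucs = np.empty(R)
    for r in range(R):
        draw = rng.choice(pool.rows, size=n, replace=False)
        _, _, aucs[r] = fit_and_score(features, draw,
                                      reg_multiplier=reg_multiplier,
                                      max_iterations=max_iterations,
                                      tolerance=tolerance,
                                      background_rows=background_rows)
    return np.sort(aucs)


def percentile_threshold(replicates: np.ndarray) -> float:
    """The ceil(0.95 R)-th smallest replicate AUC.

    For R = 100 this is exactly the 95th element of the ascending list,
    with no interpolation.
    """
    reps = np.sort(np.asarray(replicates, dtype=float))
    if reps.size == 0:
        raise DataError("empty replicate list")
    k = math.ceil(0.95 * reps.size)
    return float(reps[k - 1])


def null_model_test(observed: float, replicates: np.ndarray,
                    seed: int | None = None) -> NullModelResult:
    """Significance by strict comparison against the 95th-percentile
    order statistic of the null AUCs."""
    reps = np.sort(np.asarray(replicates, dtype=float))
    thr = percentile_threshold(reps)
    return NullModelResult(float(observed), reps, thr,
                           significant=bool(observed > thr), seed=seed)


def run_null_test(features: FeatureMatrix, presence_rows: np.ndarray,
                  pool: BackgroundPool, R: int = 100,
                  reg_multiplier: float = 1.0, max_iterations: int = 500,
                  tolerance: float = 1e-5, seed: int | None = None,
                  background_rows: np.ndarray | None = None
                  ) -> NullModelResult:
    """Fit the observed model and its null distribution in one call."""
    presence_rows = np.asarray(presence_rows)
    if presence_rows.ndim == 2:
        presence_rows = features.rows_for_cells(presence_rows)
    _, _, observed = fit_and_score(features, presence_rows,
                                   reg_multiplier=reg_multiplier,
                                   max_iterations=max_iterations,
                                   tolerance=tolerance,
                                   background_rows=background_rows)
    reps = null_auc_distribution(pool, len(presence_rows), features, R=R,
                                 reg_multiplier=reg_multiplier,
                                 max_iterations=max_iterations,
                                 tolerance=tolerance, seed=seed,
                                 background_rows=background_rows)
    return null_model_test(observed, reps, seed=seed)


def null_test_table(results: dict[str, NullModelResult],
                    n_localities: dict[str, int]) -> pd.DataFrame:
    """Per-species summary table (species, n, observed AUC, threshold,
    significant)."""
    rows = [{"species": sp, "n": n_localities[sp],
             "observed_auc": res.observed_auc, "threshold": res.threshold,
             "significant": res.significant}
            for sp, res in sorted(results.items())]
    return pd.DataFrame(rows)
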
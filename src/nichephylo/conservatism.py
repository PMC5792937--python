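"""Phylogenetic niche conservatism: overlap against phylogenetic distance.

If close relatives retain similar abiotic niches, pairwise niche
overlap (Hellinger's I) should decline with pairwise patristic
distance.  The primary statistic is the Pearson correlation over all
unordered species pairs, with a two-sided p from the t transform with
n_pairs - 2 degrees of freedom; pairs are treated as independent
observations.  Because pairwise values drawn from the same matrices are
not truly independent, a Mantel permutation test (species labels of one
matrix shuffled) is offered as a companion; it is off by default in the
pipeline.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

logger = logging.getLogger(__name__)


def paired_values(overlap: pd.DataFrame, dist: pd.DataFrame) -> pd.DataFrame:
    """One row per unordered pair of species shared by both matrices.

    Columns: species_a, species_b, overlap, distance.  Species present
    in only one matrix are dropped with a logged list.
    """
    shared = sorted(set(overlap.index) & set(dist.index))
    dropped = sorted((set(overlap.index) | set(dist.index)) - set(shared))
    if dropped:
        logger.info("paired_values: dropped species absent from one matrix: %s",
                    ", ".join(dropped))
    if len(shared) < 2:
        raise DataError("fewer than two species shared by both matrices")
    rows = [{"species_a": a, "species_b": b,
             "overlap": float(overlap.loc[a, b]),
             "distance": float(dist.loc[a, b])}
            for a, b in itertools.combinations(shared, 2)]
    return pd.DataFrame(rows)


@dataclass
class ConservatismResult:
    """Pearson correlation of niche overlap with patristic distance."""

    n_pairs: int
    r: float
    r_squared: float
    p_value: float
    species: tuple[str, ...]
    mantel_p: float | None = None
    excluded_species: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n_pairs": self.n_pairs, "r": self.r, "r_squared": self.r_squared,
            "p_value": self.p_value, "mantel_p": self.mantel_p,
            "n_species": len(self.species),
            "excluded": ";".join(self.excluded_species)}])


def pearson_test(pairs: pd.DataFrame) -> ConservatismResult:
    """Pearson r, R^2 and two-sided p over the (overlap, distance) pairs.

    The t transform with n_pairs - 2 degrees of freedom treats pairs as
    independent observations.
    """
    if len(pairs) < 3:
        raise DataError("need at least three pairs for a correlation test")
    x = pairs["overlap"].to_numpy(dtype=float)
    y = pairs["distance"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("undefined correlation: constant variable")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    species = tuple(sorted(set(pairs["species_a"]) | set(pairs["species_b"])))
    return ConservatismResult(len(pairs), r, r * r, float(res.pvalue), species)


def mantel_test(overlap: pd.DataFrame, dist: pd.DataFrame,
                n_perm: int = 999, seed: int | None = None) -> float:
    """Permutation p for the overlap-distance correlation.

    Species labels of the distance matrix are permuted; the two-sided p
    is (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm).
    """
    shared = sorted(set(overlap.index) & set(dist.index))
    if len(shared) < 4:
        raise DataError("Mantel test needs at least four shared species")
    O = overlap.loc[shared, shared].to_numpy(dtype=float)
    D = dist.loc[shared, shared].to_numpy(dtype=float)
    iu = np.triu_indices(len(shared), k=1)

    def corr(d: np.ndarray) -> float:
        return float(np.corrcoef(O[iu], d[iu])[0, 1])

    r_obs = corr(D)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(shared))
        if abs(corr(D[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-15:
            count += 1
    return (1 + count) / (1 + n_perm)


def conservatism_test(overlap: pd.DataFrame, dist: pd.DataFrame,
                      exclude: tuple[str, ...] = (),
                      run_mantel: bool = False, n_perm: int = 999,
                      seed: int | None = None) -> ConservatismResult:
    """Full conservatism test, optionally excluding species (e.g. those
    whose SDMs failed the null-model test) and adding a Mantel p."""
    keep = [s for s in overlap.index if s not in set(exclude)]
    ov = overlap.loc[keep, keep]
    result = pearson_test(paired_values(ov, dist))
    result.excluded_species = tuple(sorted(exclude))
    if run_mantel:
        result.mantel_p = mantel_test(ov, dist.loc[[s for s in dist.index
                                                    if s not in set(exclude)],
                                                   [s for s in dist.index
                                                    if s not in set(exclude)]],
                                      n_perm=n_perm, seed=seed)
    return result
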
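"""Niche overlap between suitability surfaces (Hellinger's I).

Hellinger's I compares two relative occurrence probability surfaces p
and q defined on the same grid cells:

    I(p, q) = 1 - 1/2 * sum_cells (sqrt(p) - sqrt(q))**2

I is symmetric, 1 exactly when the surfaces are identical and 0 when
their supports are disjoint.  Overlap is computed on the raw
(normalised) model output — the metric is defined on probability
distributions — and clade-level summaries report the mean +/- standard
error over within-clade and between-clade species pairs.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .errors import DataError
from .maxent_sdm import SuitabilityMap


def _as_prob_vector(p, name: str = "surface") -> np.ndarray:
    if isinstance(p, SuitabilityMap):
        p = p.probs
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise DataError(f"{name}: negative probabilities")
    s = p.sum()
    if s <= 0:
        raise DataError(f"{name}: all-zero surface")
    if abs(s - 1.0) > 1e-6:
        warnings.warn(f"{name} does not sum to 1 (sum={s:.6g}); renormalising")
        p = p / s
    return p


def hellinger_I(p, q) -> float:
    """Hellinger's I overlap between two probability surfaces on a shared
    cell set. Accepts SuitabilityMaps or probability vectors."""
    pv = _as_prob_vector(p, "p")
    qv = _as_prob_vector(q, "q")
    if pv.shape != qv.shape:
        raise DataError("surfaces are defined on different cell sets")
    if isinstance(p, SuitabilityMap) and isinstance(q, SuitabilityMap):
        if not np.array_equal(p.cell_index, q.cell_index):
            raise DataError("surfaces are defined on different cell sets")
    val = 1.0 - 0.5 * np.sum((np.sqrt(pv) - np.sqrt(qv)) ** 2)
    return float(min(1.0, max(0.0, val)))


def pairwise_overlap(maps: dict[str, SuitabilityMap | np.ndarray]) -> pd.DataFrame:
    """Symmetric matrix of Hellinger's I over all unordered pairs.

    Returns a labelled square DataFrame with unit diagonal.  When maps
    carry differing valid-cell sets, each pair is restricted to the
    intersection of cells and renormalised before comparison.
    """
    labels = list(maps)
    if len(labels) < 2:
        raise DataError("pairwise overlap needs at least two surfaces")
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        pa, pb = maps[a], maps[b]
        if (isinstance(pa, SuitabilityMap) and isinstance(pb, SuitabilityMap)
                and not np.array_equal(pa.cell_index, pb.cell_index)):
            common, ia, ib = np.intersect1d(pa.cell_index, pb.cell_index,
                                            return_indices=True)
            if common.size == 0:
                raise DataError(f"surfaces '{a}' and '{b}' share no valid cells")
            va = pa.probs[ia] / pa.probs[ia].sum()
            vb = pb.probs[ib] / pb.probs[ib].sum()
            val = hellinger_I(va, vb)
        else:
            val = hellinger_I(pa, pb)
        mat.loc[a, b] = mat.loc[b, a] = val
    return mat


def clade_overlap_summary(matrix: pd.DataFrame,
                          partition: dict[str, str],
                          spread: str = "se") -> pd.DataFrame:
    """Within- and between-clade overlap means.

    ``partition`` maps every species in the matrix to a clade/area
    label.  For each clade with >= 2 species the mean (+/- SE by default,
    or SD with spread="sd") over within-clade pairs is reported; clades
    with a single species appear with no within value.  Every unordered
    clade pair gets a between-clades row.
    """
    species = list(matrix.index)
    missing = [s for s in species if s not in partition]
    if missing:
        raise DataError(f"species missing from clade partition: {missing}")
    if spread not in ("se", "sd"):
        raise DataError("spread must be 'se' or 'sd'")

    clades: dict[str, list[str]] = {}
    for sp in species:
        clades.setdefault(partition[sp], []).append(sp)

    def summarise(values: list[float]) -> tuple[float | None, float | None]:
        if not values:
            return None, None
        mean = float(np.mean(values))
        if len(values) < 2:
            return mean, None
        sd = float(np.std(values, ddof=1))
        return mean, (sd / np.sqrt(len(values)) if spread == "se" else sd)

    rows = []
    for clade in sorted(clades):
        members = clades[clade]
        vals = [matrix.loc[a, b] for a, b in itertools.combinations(members, 2)]
        mean, err = summarise(vals)
        rows.append({"comparison": "within", "clade_a": clade, "clade_b": clade,
                     "n_species": len(members), "n_pairs": len(vals),
                     "mean_I": mean, spread: err})
    for ca, cb in itertools.combinations(sorted(clades), 2):
        vals = [matrix.loc[a, b] for a in clades[ca] for b in clades[cb]]
        mean, err = summarise(vals)
        rows.append({"comparison": "between", "clade_a": ca, "clade_b": cb,
                     "n_species": None, "n_pairs": len(vals),
                     "mean_I": mean, spread: err})
    return pd.DataFrame(rows)
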
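"""Maximum-entropy species distribution modelling over a grid-cell domain.

The model is the Gibbs distribution over grid cells closest to uniform
(maximum entropy) subject to matching the empirical averages of
environmental features at the presence localities.  Equivalently, the
feature weights lambda maximise the L1-penalised presence
log-likelihood of

    P(cell) = exp(lambda . f(cell)) / Z(lambda)

over the background cells.  The raw output is this relative occurrence
probability per cell, normalised to sum to 1 over the study area.

Feature construction follows the conventions of the reference Maxent
software: continuous layers are min-max scaled to [0, 1] over the valid
domain; "auto" feature classes switch on with presence sample size
(linear always, quadratic at >= 10, hinge at >= 15, threshold and
product at >= 80); categorical layers expand into one 0/1 indicator per
observed category.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .errors import DataError, NumericalError
from .geodata import CATEGORICAL, CONTINUOUS, EnvStack, RasterGrid

logger = logging.getLogger(__name__)

#: auto-feature activation thresholds on the presence count
AUTO_THRESHOLDS = {"linear": 1, "quadratic": 10, "hinge": 15,
                   "threshold": 80, "product": 80}

#: default per-class L1 penalty constants (configurable)
DEFAULT_BETA = {"linear": 1.0, "quadratic": 1.0, "product": 1.0,
                "hinge": 0.5, "threshold": 1.0, "category": 0.25}

#: maximum background size before seed-controlled subsampling
MAX_BACKGROUND = 10_000

#: hinge/threshold knots per layer (hinge: split between both orientations)
N_KNOTS = 50

#: hard cap on |weight| used to flag separation under zero penalty
WEIGHT_CAP = 100.0


@dataclass
class FeatureDescriptor:
    """One model feature: its class, source layer(s) and knot/category."""
    kind: str                       # linear|quadratic|product|hinge|threshold|category
    layer: str
    layer2: str | None = None      # product features only
    knot: float | None = None      # hinge/threshold knot in scaled units
    orientation: str | None = None  # hinge: "forward" | "reverse"
    category: int | None = None    # category indicators only

    def label(self) -> str:
        if self.kind == "product":
            return f"product({self.layer}*{self.layer2})"
        if self.kind == "hinge":
            return f"hinge_{self.orientation}({self.layer}@{self.knot:.4g})"
        if self.kind == "threshold":
            return f"threshold({self.layer}@{self.knot:.4g})"
        if self.kind == "category":
            return f"category({self.layer}={self.category})"
        return f"{self.kind}({self.layer})"


@dataclass
class FeatureMatrix:
    """Feature values over the valid cells of a stack.

    ``X`` has one row per valid cell (in ascending flattened cell order)
    and one column per feature; continuous-derived features live in
    [0, 1] and indicators are 0/1.  ``cell_index`` maps rows to flat
    grid indices; ``scale`` records the (min, max) used per continuous
    layer so a fitted model can be re-applied.
    """

    X: np.ndarray
    descriptors: list[FeatureDescriptor]
    cell_index: np.ndarray
    scale: dict[str, tuple[float, float]]
    grid_shape: tuple[int, int]
    grid: RasterGrid | None = None

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.descriptors):
            raise DataError("feature matrix width disagrees with descriptor list")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def rows_for_cells(self, cells: np.ndarray) -> np.ndarray:
        """Translate (row, col) pairs into row indices of X."""
        cells = np.asarray(cells)
        flat = cells[:, 0] * self.grid_shape[1] + cells[:, 1]
        pos = np.searchsorted(self.cell_index, flat)
        ok = (pos < len(self.cell_index)) & (self.cell_index[np.minimum(pos, len(self.cell_index) - 1)] == flat)
        if not ok.all():
            raise DataError("presence cell on a masked or out-of-domain cell")
        return pos


def auto_feature_classes(n_presences: int) -> list[str]:
    """Feature classes enabled by presence count under 'auto features'."""
    return [k for k, thr in AUTO_THRESHOLDS.items() if n_presences >= thr]


def build_features(stack: EnvStack, n_presences: int,
                   mode: str | Sequence[str] = "auto",
                   n_knots: int = N_KNOTS) -> FeatureMatrix:
    """Expand an environmental stack into a Maxent feature matrix.

    ``mode`` is either "auto" (classes chosen from ``n_presences``) or an
    explicit list of feature class names.  Hinge knots are evenly spaced
    over the scaled [0, 1] range, half forward and half reverse;
    threshold knots are evenly spaced step indicators.
    """
    if n_presences < 1:
        raise DataError("n_presences must be >= 1")
    if isinstance(mode, str) and mode == "auto":
        classes = auto_feature_classes(n_presences)
    else:
        classes = list(mode)
        unknown = set(classes) - set(AUTO_THRESHOLDS)
        if unknown:
            raise DataError(f"unknown feature classes: {sorted(unknown)}")

    values = stack.valid_values()
    cols: list[np.ndarray] = []
    desc: list[FeatureDescriptor] = []
    scale: dict[str, tuple[float, float]] = {}

    cont = [(i, stack.names[i]) for i in range(stack.n_layers)
            if stack.kinds[i] == CONTINUOUS]
    cat = [(i, stack.names[i]) for i in range(stack.n_layers)
           if stack.kinds[i] == CATEGORICAL]

    scaled: dict[str, np.ndarray] = {}
    for i, name in cont:
        v = values[:, i]
        lo, hi = float(v.min()), float(v.max())
        scale[name] = (lo, hi)
        scaled[name] = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)

    if "linear" in classes:
        for _, name in cont:
            cols.append(scaled[name])
            desc.append(FeatureDescriptor("linear", name))
    if "quadratic" in classes:
        for _, name in cont:
            cols.append(scaled[name] ** 2)
            desc.append(FeatureDescriptor("quadratic", name))
    if "product" in classes:
        for a in range(len(cont)):
            for b in range(a + 1, len(cont)):
                na, nb = cont[a][1], cont[b][1]
                cols.append(scaled[na] * scaled[nb])
                desc.append(FeatureDescriptor("product", na, layer2=nb))
    if "hinge" in classes:
        half = max(1, n_knots // 2)
        knots = np.linspace(0.0, 1.0, half + 2)[1:-1]
        for _, name in cont:
            v = scaled[name]
            for k in knots:
                cols.append(np.maximum(v - k, 0.0) / (1.0 - k))
                desc.append(FeatureDescriptor("hinge", name, knot=float(k),
                                              orientation="forward"))
                cols.append(np.maximum(k - v, 0.0) / k)
                desc.append(FeatureDescriptor("hinge", name, knot=float(k),
                                              orientation="reverse"))
    if "threshold" in classes:
        knots = np.linspace(0.0, 1.0, n_knots + 2)[1:-1]
        for _, name in cont:
            v = scaled[name]
            for k in knots:
                cols.append((v >= k).astype(float))
                desc.append(FeatureDescriptor("threshold", name, knot=float(k)))

    for i, name in cat:
        codes = np.unique(values[:, i]).astype(int)
        if len(codes) < 2:
            warnings.warn(f"categorical layer '{name}' has a single category; "
                          "indicator dropped (constant feature)")
            continue
        for code in codes:
            cols.append((values[:, i].astype(int) == code).astype(float))
            desc.append(FeatureDescriptor("category", name, category=int(code)))

    if not cols:
        raise DataError("no features produced (empty class list or all-constant layers)")
    X = np.column_stack(cols)
    return FeatureMatrix(X, desc, stack.valid_cell_indices(), scale,
                         (stack.grid.n_rows, stack.grid.n_cols), grid=stack.grid)


@dataclass
class MaxentModel:
    """Fitted maximum-entropy model: weights, penalties and diagnostics."""

    descriptors: list[FeatureDescriptor]
    weights: np.ndarray
    log_normalizer: float
    reg_multiplier: float
    penalties: np.ndarray
    n_iterations: int
    converged: bool
    background_rows: np.ndarray
    seed: int | None = None

    def linear_predictor(self, features: FeatureMatrix) -> np.ndarray:
        if len(features.descriptors) != len(self.descriptors):
            raise DataError("feature matrix does not match model descriptors")
        labels_a = [d.label() for d in features.descriptors]
        labels_b = [d.label() for d in self.descriptors]
        if labels_a != labels_b:
            raise DataError("feature descriptors disagree with the model's")
        return features.X @ self.weights


def default_penalties(features: FeatureMatrix, presence_rows: np.ndarray,
                      reg_multiplier: float,
                      beta_table: dict[str, float] | None = None) -> np.ndarray:
    """Per-feature L1 penalty: reg * beta_class * s_j / sqrt(m).

    ``s_j`` is the presence-sample standard deviation of feature j and m
    the presence count, so rarely-varying features are penalised less and
    penalties vanish as the sample grows.  ``s_j`` is floored at
    1/sqrt(m): a feature constant across the presence sample would
    otherwise carry no penalty at all and its weight would diverge
    whenever the constraint is only attainable in the limit (complete
    separation).
    """
    beta = dict(DEFAULT_BETA)
    if beta_table:
        beta.update(beta_table)
    m = len(presence_rows)
    s = np.maximum(features.X[presence_rows].std(axis=0), 1.0 / np.sqrt(m))
    cls = np.array([beta[d.kind] for d in features.descriptors])
    return reg_multiplier * cls * s / np.sqrt(m)


def fit_maxent(features: FeatureMatrix, presence_cells: np.ndarray,
               reg_multiplier: float = 1.0, max_iterations: int = 500,
               tolerance: float = 1e-5, seed: int | None = None,
               beta_table: dict[str, float] | None = None,
               background_rows: np.ndarray | None = None) -> MaxentModel:
    """Fit the penalised maximum-entropy model.

    ``presence_cells`` is either an (n, 2) array of (row, col) grid cells
    or a 1-D array of row indices into the feature matrix.  The
    background defaults to all valid cells, subsampled to at most
    ``MAX_BACKGROUND`` cells under the given seed.

    The L1-penalised concave log-likelihood is maximised by splitting
    each weight into its positive and negative parts, which turns the
    kinked objective into a smooth bound-constrained one solved with
    L-BFGS-B; iteration stops at a projected-gradient tolerance
    (default 1e-5) or ``max_iterations``.
    """
    presence_cells = np.asarray(presence_cells)
    if presence_cells.size == 0:
        raise DataError("at least one presence cell is required")
    if presence_cells.ndim == 2:
        presence_rows = features.rows_for_cells(presence_cells)
    else:
        presence_rows = presence_cells.astype(int)
        if presence_rows.max() >= features.n_cells or presence_rows.min() < 0:
            raise DataError("presence row index outside the valid domain")

    if background_rows is None:
        if features.n_cells <= MAX_BACKGROUND:
            background_rows = np.arange(features.n_cells)
        else:
            rng = np.random.default_rng(seed)
            background_rows = np.sort(rng.choice(features.n_cells, MAX_BACKGROUND,
                                                 replace=False))

    F_bg = features.X[background_rows]
    p_bar = features.X[presence_rows].mean(axis=0)
    beta_j = default_penalties(features, presence_rows, reg_multiplier, beta_table)

    k = features.n_features

    # objective in split variables u = (a, b), lambda = a - b, a,b >= 0:
    #   logZ(lambda) - lambda.p_bar + beta.(a + b)   (to be minimised)
    def objective(u: np.ndarray) -> tuple[float, np.ndarray]:
        lam = u[:k] - u[k:]
        eta = F_bg @ lam
        log_z = logsumexp(eta)
        w = np.exp(eta - log_z)
        e_model = w @ F_bg
        val = log_z - lam @ p_bar + beta_j @ (u[:k] + u[k:])
        g = e_model - p_bar
        grad = np.concatenate([g + beta_j, -g + beta_j])
        return val, grad

    u0 = np.zeros(2 * k)
    res = minimize(objective, u0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, WEIGHT_CAP)] * (2 * k),
                   options={"maxiter": max_iterations, "maxfun": 10 * max_iterations,
                            "gtol": tolerance, "ftol": 1e-14})
    lam = res.x[:k] - res.x[k:]
    capped = np.any(np.abs(lam) >= WEIGHT_CAP - 1e-6)
    # complete separation: an unpenalised feature whose presence mean sits on
    # the boundary of the attainable moment set (its background min or max)
    # can only satisfy the constraint in the limit |lambda| -> inf
    bg_min, bg_max = F_bg.min(axis=0), F_bg.max(axis=0)
    separated = np.any((beta_j <= 0) & (bg_max > bg_min)
                       & ((p_bar >= bg_max - 1e-12) | (p_bar <= bg_min + 1e-12)))
    converged = bool(res.success) and not capped and not separated
    if capped or separated:
        warnings.warn("complete separation under zero penalty: the moment "
                      "constraint is only attainable in the limit; weights "
                      "capped and fit flagged non-converged")
    if not np.all(np.isfinite(lam)):
        raise NumericalError("non-finite weights in maxent fit")
    log_z = float(logsumexp(F_bg @ lam))
    return MaxentModel(features.descriptors, lam, log_z, reg_multiplier,
                       beta_j, int(res.nit), converged, background_rows, seed)


@dataclass
class SuitabilityMap:
    """Per-cell relative occurrence probability (Maxent raw output).

    ``probs`` sums to 1 over the valid cells; ``grid`` embeds the values
    in the source raster geometry with nodata elsewhere.
    """

    probs: np.ndarray
    cell_index: np.ndarray
    grid_shape: tuple[int, int]
    grid: RasterGrid | None = None

    def as_raster(self, template: RasterGrid | None = None) -> RasterGrid:
        template = template or self.grid
        if template is None:
            raise DataError("no raster template available")
        vals = np.full(self.grid_shape, np.nan)
        mask = np.ones(self.grid_shape, dtype=bool)
        rows, cols = np.unravel_index(self.cell_index, self.grid_shape)
        vals[rows, cols] = self.probs
        mask[rows, cols] = False
        return RasterGrid(vals, mask, template.x_min, template.y_min,
                          template.cell_size, name="suitability")


def predict_raw(model: MaxentModel, features: FeatureMatrix) -> SuitabilityMap:
    """Raw relative-probability surface: softmax of the linear predictor
    over all valid cells (sums to 1)."""
    eta = model.linear_predictor(features)
    eta = eta - eta.max()
    w = np.exp(eta)
    probs = w / w.sum()
    return SuitabilityMap(probs, features.cell_index, features.grid_shape,
                          grid=features.grid)


def compute_auc(presence_scores: Sequence[float],
                background_scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC: the probability that a random
    presence outscores a random background cell, ties counting 0.5."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise DataError("AUC needs non-empty presence and background scores")
    from scipy.stats import rankdata
    ranks = rankdata(np.concatenate([p, b]))
    r1 = ranks[:p.size].sum()
    u = r1 - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def fit_and_score(features: FeatureMatrix, presence_rows: np.ndarray,
                  reg_multiplier: float = 1.0, max_iterations: int = 500,
                  tolerance: float = 1e-5, seed: int | None = None,
                  background_rows: np.ndarray | None = None
                  ) -> tuple[MaxentModel, SuitabilityMap, float]:
    """Fit, predict and AUC-score one species in a single call."""
    presence_rows = np.asarray(presence_rows)
    if presence_rows.ndim == 2:
        presence_rows = features.rows_for_cells(presence_rows)
    model = fit_maxent(features, presence_rows, reg_multiplier=reg_multiplier,
                       max_iterations=max_iterations, tolerance=tolerance,
                       seed=seed, background_rows=background_rows)
    smap = predict_raw(model, features)
    auc = compute_auc(smap.probs[presence_rows.astype(int)],
                      smap.probs[model.background_rows])
    return model, smap, auc


def save_model(model: MaxentModel, path: str | Path) -> None:
    """Serialise a model as a plain-text feature/weight table with a
    metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# maxent model\n")
        fh.write(f"# reg_multiplier\t{model.reg_multiplier}\n")
        fh.write(f"# log_normalizer\t{model.log_normalizer:.12g}\n")
        fh.write(f"# n_iterations\t{model.n_iterations}\n")
        fh.write(f"# converged\t{model.converged}\n")
        fh.write("feature\tweight\tpenalty\n")
        for d, w, b in zip(model.descriptors, model.weights, model.penalties):
            fh.write(f"{d.label()}\t{w:.12g}\t{b:.12g}\n")
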
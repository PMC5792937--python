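"""Synthetic worlds with known truth for end-to-end testing.

Generates everything the pipeline consumes: a stack of smooth,
spatially autocorrelated continuous layers plus patchy categorical
layers; a clock-like (pure-birth, depth-1) phylogeny; species niche
optima evolving by Brownian motion along that phylogeny; presence
records sampled in proportion to Gaussian niche suitability; and a
pooled target-group background of unique localities.  Because the
niche optima of close relatives are correlated by construction, the
full pipeline applied to a default world should recover a negative
overlap-distance correlation; shuffling optima across tips destroys
that signal and provides the matching null condition.

Defaults describe a moderate desk-scale study: a 64x64 fully valid
grid, four continuous and one categorical layer, 16 tips, 30 records
per species, Brownian rate sigma2 = 0.05 (tip spread sd ~0.22 on
[0,1]-scaled layers) and niche breadth tau = 0.15 — optima diverge on
the same scale as the niche breadth, the regime the conservatism test
is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import DataError
from .geodata import (CATEGORICAL, CONTINUOUS, EnvStack, OccurrenceSet,
                      RasterGrid, write_ascii_grid, write_occurrences)
from .phylo_metrics import PhyloTree, read_tree


def make_env_stack(n_rows: int = 64, n_cols: int = 64, n_continuous: int = 4,
                   n_categorical: int = 1, smoothness: float = 6.0,
                   n_categories: int = 4, seed: int | None = None,
                   x_min: float = 0.0, y_min: float = 0.0,
                   cell_size: float = 1.0) -> EnvStack:
    """Smooth random continuous layers plus patchy categorical layers.

    Continuous layers are Gaussian-blurred white noise (blur sigma =
    ``smoothness`` cells) min-max scaled to [0, 1]; categorical layers
    are nearest-centre (Voronoi) patches with ``n_categories`` codes.
    All cells are valid.
    """
    if n_rows < 8 or n_cols < 8:
        raise DataError("grid must be at least 8x8")
    if n_continuous + n_categorical < 1:
        raise DataError("at least one layer required")
    rng = np.random.default_rng(seed)
    layers: list[RasterGrid] = []
    kinds: list[str] = []
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    for i in range(n_continuous):
        noise = rng.standard_normal((n_rows, n_cols))
        smooth = gaussian_filter(noise, sigma=smoothness, mode="reflect")
        lo, hi = smooth.min(), smooth.max()
        vals = (smooth - lo) / (hi - lo) if hi > lo else np.full_like(smooth, 0.5)
        layers.append(RasterGrid(vals, mask.copy(), x_min, y_min, cell_size,
                                 name=f"env{i + 1}"))
        kinds.append(CONTINUOUS)
    for i in range(n_categorical):
        centres = rng.uniform(size=(n_categories, 2)) * [n_rows, n_cols]
        rr, cc = np.mgrid[0:n_rows, 0:n_cols]
        d2 = ((rr[..., None] - centres[:, 0]) ** 2
              + (cc[..., None] - centres[:, 1]) ** 2)
        codes = d2.argmin(axis=-1).astype(float)
        layers.append(RasterGrid(codes, mask.copy(), x_min, y_min, cell_size,
                                 name=f"soil{i + 1}"))
        kinds.append(CATEGORICAL)
    return EnvStack(layers, kinds)


def simulate_tree(n_tips: int = 16, seed: int | None = None) -> PhyloTree:
    """Pure-birth (Yule) tree rescaled to depth 1; tips sp01, sp02, ...

    Inter-branching waiting times are exponential with rate equal to
    the current lineage count; the lineage to split is chosen uniformly.
    All pendant branches are extended to the present, so the tree is
    exactly ultrametric.
    """
    if n_tips < 2:
        raise DataError("need at least two tips")
    rng = np.random.default_rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    # active lineages: (node, birth_time of its pendant edge start)
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    active = [(c1, 0.0), (c2, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        node, born = active.pop(idx)
        node.edge.length = t - born
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        active.append((a, t))
        active.append((b, t))
    t_end = t + rng.exponential(1.0 / len(active))
    for node, born in active:
        node.edge.length = t_end - born
    # name tips in a reproducible left-to-right order
    width = len(str(n_tips))
    for k, leaf in enumerate(tree.leaf_node_iter()):
        label = f"sp{k + 1:0{width}d}"
        leaf.taxon = taxon_ns.new_taxon(label)
    root.edge.length = 0.0
    # rescale to depth 1
    depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length:
            edge.length = edge.length / depth
    return read_tree(tree.as_string(schema="newick"))


def evolve_niches(tree: PhyloTree, sigma2: float = 0.05,
                  root_optimum: np.ndarray | None = None, n_dims: int = 2,
                  seed: int | None = None) -> dict[str, np.ndarray]:
    """Brownian-motion niche optima along the tree, per dimension.

    Each branch adds Normal(0, sigma2 * branch_length) noise
    independently per niche dimension, so tip covariance equals sigma2
    times shared path length.  Returns tip label -> optimum vector.
    """
    if sigma2 < 0:
        raise DataError("sigma2 must be non-negative")
    root_optimum = (np.full(n_dims, 0.5) if root_optimum is None
                    else np.asarray(root_optimum, dtype=float))
    n_dims = len(root_optimum)
    rng = np.random.default_rng(seed)
    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = root_optimum.copy()
        else:
            bl = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(sigma2 * bl), size=n_dims)
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def sample_occurrences(env: EnvStack, optima: dict[str, np.ndarray],
                       tau: float = 0.15, n_per_species: int = 30,
                       seed: int | None = None,
                       niche_layers: list[str] | None = None) -> OccurrenceSet:
    """Presence records sampled proportionally to Gaussian suitability.

    Cell weight is exp(-||e(cell) - optimum||^2 / (2 tau^2)) over the
    designated continuous niche layers (default: the first k continuous
    layers, k = optimum dimension).  Cells are drawn without replacement
    per species; records are placed at cell centres.
    """
    if tau <= 0:
        raise DataError("tau must be positive")
    if n_per_species < 1:
        raise DataError("n_per_species must be >= 1")
    if n_per_species > env.n_valid_cells:
        raise DataError("n_per_species exceeds the number of valid cells")
    n_dims = len(next(iter(optima.values())))
    if niche_layers is None:
        cont = [n for n, k in zip(env.names, env.kinds) if k == CONTINUOUS]
        if len(cont) < n_dims:
            raise DataError("not enough continuous layers for the niche dimension")
        niche_layers = cont[:n_dims]
    cols = [env.names.index(n) for n in niche_layers]
    values = env.valid_values()[:, cols]
    flat_idx = env.valid_cell_indices()
    grid = env.grid
    rng = np.random.default_rng(seed)
    frames = []
    for sp in sorted(optima):
        opt = np.asarray(optima[sp], dtype=float)
        d2 = ((values - opt) ** 2).sum(axis=1)
        logw = -d2 / (2 * tau * tau)
        w = np.exp(logw - logw.max())
        p = w / w.sum()
        chosen = rng.choice(len(p), size=n_per_species, replace=False, p=p)
        rows, cls = np.unravel_index(flat_idx[chosen], (grid.n_rows, grid.n_cols))
        xy = [grid.cell_center(r, c) for r, c in zip(rows, cls)]
        frames.append(pd.DataFrame({
            "species": sp,
            "longitude": [x for x, _ in xy],
            "latitude": [y for _, y in xy]}))
    return OccurrenceSet(pd.concat(frames, ignore_index=True))


@dataclass
class SyntheticWorld:
    """A complete generated study system with known truth."""

    env: EnvStack
    tree: PhyloTree
    optima: dict[str, np.ndarray]
    tau: float
    occurrences: OccurrenceSet
    params: dict = field(default_factory=dict)
    seed: int | None = None


def make_background_pool_cells(world: SyntheticWorld, mode: str = "union",
                               n_pool: int | None = None,
                               seed: int | None = None) -> np.ndarray:
    """Background-pool cells as (row, col) pairs.

    "union" pools the unique cells of all species' occurrences
    (emulating a target-group collection database); "uniform" draws
    ``n_pool`` unique valid cells uniformly.
    """
    from .geodata import assign_cells, deduplicate
    if mode == "union":
        occ = deduplicate(assign_cells(world.occurrences, world.env.grid,
                                       mask=world.env.mask))
        cells = occ.records[["row", "col"]].drop_duplicates().to_numpy(dtype=int)
        if cells.size == 0:
            raise DataError("empty pool union")
        return cells
    if mode == "uniform":
        if n_pool is None:
            raise DataError("uniform mode requires n_pool")
        if n_pool > world.env.n_valid_cells:
            raise DataError("n_pool exceeds the number of valid cells")
        rng = np.random.default_rng(seed)
        flat = rng.choice(world.env.valid_cell_indices(), size=n_pool,
                          replace=False)
        rows, cols = np.unravel_index(flat, (world.env.grid.n_rows,
                                             world.env.grid.n_cols))
        return np.column_stack([rows, cols])
    raise DataError(f"unknown pool mode '{mode}'")


def make_world(n_rows: int = 64, n_cols: int = 64, n_continuous: int = 4,
               n_categorical: int = 1, n_tips: int = 16, sigma2: float = 0.05,
               tau: float = 0.15, n_per_species: int = 30,
               smoothness: float = 6.0, n_niche_dims: int = 2,
               seed: int | None = None,
               shuffle_tips: bool = False) -> SyntheticWorld:
    """Generate a complete world under one master seed.

    With ``shuffle_tips`` the evolved optima are randomly reassigned to
    tips, detaching niches from phylogeny — the null condition for the
    conservatism test.
    """
    rng = np.random.default_rng(seed)
    s_env, s_tree, s_bm, s_occ, s_shuf = rng.integers(2 ** 31, size=5)
    env = make_env_stack(n_rows, n_cols, n_continuous, n_categorical,
                         smoothness=smoothness, seed=int(s_env))
    tree = simulate_tree(n_tips, seed=int(s_tree))
    optima = evolve_niches(tree, sigma2=sigma2, n_dims=n_niche_dims,
                           seed=int(s_bm))
    if shuffle_tips:
        rng2 = np.random.default_rng(int(s_shuf))
        labels = sorted(optima)
        vals = [optima[l] for l in labels]
        perm = rng2.permutation(len(labels))
        optima = {labels[i]: vals[perm[i]] for i in range(len(labels))}
    occ = sample_occurrences(env, optima, tau=tau,
                             n_per_species=n_per_species, seed=int(s_occ))
    params = dict(n_rows=n_rows, n_cols=n_cols, n_continuous=n_continuous,
                  n_categorical=n_categorical, n_tips=n_tips, sigma2=sigma2,
                  tau=tau, n_per_species=n_per_species, smoothness=smoothness,
                  n_niche_dims=n_niche_dims, shuffle_tips=shuffle_tips)
    return SyntheticWorld(env, tree, optima, tau, occ, params=params, seed=seed)


def write_world(world: SyntheticWorld, out_dir: str | Path) -> None:
    """Write a world to disk: ESRI ASCII rasters, occurrence/pool CSVs,
    Newick tree and a truth table of optima."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    env_dir = out / "env"
    env_dir.mkdir(exist_ok=True)
    for grid, kind, name in zip(world.env.layers, world.env.kinds,
                                world.env.names):
        write_ascii_grid(grid, env_dir / f"{name}.asc")
    (out / "layer_kinds.csv").write_text(
        "layer,kind\n" + "\n".join(f"{n},{k}" for n, k in
                                   zip(world.env.names, world.env.kinds)) + "\n")
    write_occurrences(world.occurrences, out / "occurrences.csv")
    pool = make_background_pool_cells(world, mode="union")
    grid = world.env.grid
    xy = [grid.cell_center(r, c) for r, c in pool]
    pd.DataFrame({"longitude": [x for x, _ in xy],
                  "latitude": [y for _, y in xy]}).to_csv(
        out / "pool.csv", index=False)
    (out / "tree.nwk").write_text(world.tree.tree.as_string(schema="newick"))
    truth = pd.DataFrame({sp: opt for sp, opt in world.optima.items()}).T
    truth.columns = [f"optimum_{i + 1}" for i in range(truth.shape[1])]
    truth.index.name = "species"
    truth.to_csv(out / "truth_optima.csv")
    pd.Series(world.params).to_json(out / "params.json")
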
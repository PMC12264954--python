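"""Similarity x affinity-difference threshold-grid evaluation.

The structure-activity landscape of a test set is summarized on a grid of
(similarity threshold s, affinity-difference threshold a) cells. Under the
default *cumulative* semantics a cell holds every test pair whose best
similarity criterion is >= s AND whose affinity difference is >= a, so the
pair population shrinks monotonically toward the high-similarity /
high-difference corner where the hardest activity cliffs live. An
alternative *disjoint* interval-binning semantics (each pair in exactly one
cell) is available behind a flag.

The grid metric is the micro- or macro-averaged RMSE of the DTI model over
the UNIQUE (compound, target) interactions touched by the member pairs —
an interaction shared by several pairs in a cell is counted once. Cells
with fewer pairs than ``min_pairs`` (default 100) are masked as
statistically unreliable.

Repeated training runs are aggregated cellwise as mean +/- sample standard
deviation, and transfer learning is judged by the differential grid
``baseline - transfer``: positive cells mean the transfer model achieved
the lower RMSE there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ac_mining import CompoundPair
from .metrics import rmse_macro, rmse_micro

DEFAULT_MIN_PAIRS = 100


def _check_axes(sim_thresholds, aff_thresholds):
    s = np.asarray(sim_thresholds, dtype=float)
    a = np.asarray(aff_thresholds, dtype=float)
    if s.size == 0 or a.size == 0:
        raise ValueError("grid axes must be non-empty")
    if np.any(np.diff(s) <= 0) or np.any(np.diff(a) <= 0):
        raise ValueError("grid axes must be strictly ascending")
    return s, a


@dataclass
class ThresholdGrid:
    """Per-cell metric, pair/interaction counts and mask on fixed axes.

    Arrays are indexed ``[i_sim, j_aff]``. ``metric_std`` is zero for a
    single-run grid and the sample std after :func:`aggregate_repeats`.
    """

    sim_thresholds: np.ndarray
    aff_thresholds: np.ndarray
    metric_mean: np.ndarray
    metric_std: np.ndarray
    pair_count: np.ndarray
    interaction_count: np.ndarray
    masked: np.ndarray
    min_pairs: int = DEFAULT_MIN_PAIRS
    metric: str = "rmse_micro"
    cumulative: bool = True
    n_repeats: int = 1

    def __post_init__(self):
        self.sim_thresholds, self.aff_thresholds = _check_axes(
            self.sim_thresholds, self.aff_thresholds)
        if self.cumulative:
            pc = self.pair_count
            if (np.any(np.diff(pc, axis=0) > 0)
                    or np.any(np.diff(pc, axis=1) > 0)):
                raise AssertionError(
                    "cumulative pair counts must be non-increasing along "
                    "both axes")

    def same_axes(self, other: "ThresholdGrid") -> bool:
        return (np.array_equal(self.sim_thresholds, other.sim_thresholds)
                and np.array_equal(self.aff_thresholds, other.aff_thresholds))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per cell."""
        rows = []
        for i, s in enumerate(self.sim_thresholds):
            for j, a in enumerate(self.aff_thresholds):
                rows.append({
                    "sim_threshold": s, "aff_threshold": a,
                    "mean": self.metric_mean[i, j],
                    "std": self.metric_std[i, j],
                    "pair_count": int(self.pair_count[i, j]),
                    "interaction_count": int(self.interaction_count[i, j]),
                    "masked": bool(self.masked[i, j]),
                })
        return pd.DataFrame(rows)


@dataclass
class DifferentialGrid:
    """Cellwise baseline-minus-transfer differences; positive = transfer wins."""

    sim_thresholds: np.ndarray
    aff_thresholds: np.ndarray
    delta_mean: np.ndarray
    propagated_std: np.ndarray
    masked: np.ndarray
    metric: str = "rmse_micro"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sim_thresholds):
            for j, a in enumerate(self.aff_thresholds):
                rows.append({
                    "sim_threshold": s, "aff_threshold": a,
                    "delta_mean": self.delta_mean[i, j],
                    "propagated_std": self.propagated_std[i, j],
                    "masked": bool(self.masked[i, j]),
                })
        return pd.DataFrame(rows)


def assign_pairs_to_cells(test_pairs: list[CompoundPair], sim_thresholds,
                          aff_thresholds, cumulative: bool = True):
    """Map each grid cell (i, j) to the indices of its member pairs.

    Cumulative: pair in cell iff max-criterion similarity >= s_i and
    delta_affinity >= a_j. Disjoint: pair in the single cell whose
    half-open interval [threshold, next threshold) contains it on both
    axes; pairs below the first threshold on either axis belong to no cell.
    """
    s, a = _check_axes(sim_thresholds, aff_thresholds)
    cells = {(i, j): [] for i in range(len(s)) for j in range(len(a))}
    for idx, pair in enumerate(test_pairs):
        sim = pair.similarity.max()
        delta = pair.delta_affinity
        if cumulative:
            for i in range(len(s)):
                if sim < s[i]:
                    break
                for j in range(len(a)):
                    if delta < a[j]:
                        break
                    cells[(i, j)].append(idx)
        else:
            i = int(np.searchsorted(s, sim, side="right")) - 1
            j = int(np.searchsorted(a, delta, side="right")) - 1
            if i >= 0 and j >= 0:
                cells[(i, j)].append(idx)
    return cells


def grid_metric(test_pairs: list[CompoundPair], predictions: dict,
                sim_thresholds, aff_thresholds, metric: str = "rmse_micro",
                min_pairs: int = DEFAULT_MIN_PAIRS,
                cumulative: bool = True) -> ThresholdGrid:
    """Per-cell RMSE of the DTI predictions over unique member interactions.

    ``predictions`` maps ``(compound_id, target_id)`` to a
    ``(true_affinity, predicted_affinity)`` tuple and must cover every
    interaction referenced by a member pair.
    """
    if metric not in ("rmse_micro", "rmse_macro"):
        raise ValueError("metric must be rmse_micro or rmse_macro")
    s, a = _check_axes(sim_thresholds, aff_thresholds)
    cells = assign_pairs_to_cells(test_pairs, s, a, cumulative=cumulative)
    fn = rmse_micro if metric == "rmse_micro" else rmse_macro
    shape = (len(s), len(a))
    mean = np.full(shape, np.nan)
    pair_count = np.zeros(shape, dtype=int)
    inter_count = np.zeros(shape, dtype=int)
    for (i, j), idxs in cells.items():
        pair_count[i, j] = len(idxs)
        if not idxs:
            continue
        interactions = set()
        for idx in idxs:
            p = test_pairs[idx]
            interactions.add((p.compound_a, p.target_id))
            interactions.add((p.compound_b, p.target_id))
        targets, y_true, y_pred = [], [], []
        for key in sorted(interactions):
            if key not in predictions:
                raise KeyError(f"no prediction for interaction {key}")
            yt, yp = predictions[key]
            targets.append(key[1])
            y_true.append(yt)
            y_pred.append(yp)
        inter_count[i, j] = len(interactions)
        mean[i, j] = fn(targets, y_true, y_pred)
    masked = pair_count < min_pairs
    return ThresholdGrid(sim_thresholds=s, aff_thresholds=a, metric_mean=mean,
                         metric_std=np.zeros(shape), pair_count=pair_count,
                         interaction_count=inter_count, masked=masked,
                         min_pairs=min_pairs, metric=metric,
                         cumulative=cumulative)


def aggregate_repeats(grids: list[ThresholdGrid]) -> ThresholdGrid:
    """Cellwise mean and sample standard deviation over repeated runs."""
    if not grids:
        raise ValueError("no grids to aggregate")
    first = grids[0]
    for g in grids[1:]:
        if not first.same_axes(g):
            raise ValueError("grid axes differ across repeats")
        if not np.array_equal(first.masked, g.masked):
            raise ValueError("grid masks differ across repeats")
    stack = np.stack([g.metric_mean for g in grids])
    if len(grids) == 1:
        warnings.warn("single grid: std reported as 0")
        std = np.zeros_like(first.metric_mean)
    else:
        std = np.std(stack, axis=0, ddof=1)
    return ThresholdGrid(
        sim_thresholds=first.sim_thresholds,
        aff_thresholds=first.aff_thresholds,
        metric_mean=np.mean(stack, axis=0), metric_std=std,
        pair_count=first.pair_count.copy(),
        interaction_count=first.interaction_count.copy(),
        masked=first.masked.copy(), min_pairs=first.min_pairs,
        metric=first.metric, cumulative=first.cumulative,
        n_repeats=len(grids))


def differential(baseline: ThresholdGrid,
                 transfer: ThresholdGrid) -> DifferentialGrid:
    """Baseline minus transfer per cell; masks OR-ed; stds added in quadrature.

    Positive cells mean the transfer-learning model achieved the lower RMSE
    (RMSE is a loss, so subtracting the transfer value from the baseline
    makes improvement positive).
    """
    if not baseline.same_axes(transfer):
        raise ValueError("differential requires identical grid axes")
    return DifferentialGrid(
        sim_thresholds=baseline.sim_thresholds,
        aff_thresholds=baseline.aff_thresholds,
        delta_mean=baseline.metric_mean - transfer.metric_mean,
        propagated_std=np.sqrt(baseline.metric_std ** 2
                               + transfer.metric_std ** 2),
        masked=baseline.masked | transfer.masked,
        metric=baseline.metric)


def plot_grid(grid, path=None, ax=None, title=None):
    """Render a (differential) grid as a heatmap; masked cells in gray.

    Differential grids use a diverging palette centered at zero with
    positive (transfer better) shown in blue.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    is_diff = isinstance(grid, DifferentialGrid)
    values = grid.delta_mean if is_diff else grid.metric_mean
    data = np.ma.masked_where(grid.masked | np.isnan(values), values)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    if is_diff:
        vmax = np.nanmax(np.abs(data)) or 1.0
        im = ax.imshow(data.T, origin="lower", cmap="RdBu",
                       vmin=-vmax, vmax=vmax, aspect="auto")
    else:
        im = ax.imshow(data.T, origin="lower", cmap="viridis", aspect="auto")
    im.cmap.set_bad("lightgray")
    ax.set_xticks(range(len(grid.sim_thresholds)),
                  [f"{v:g}" for v in grid.sim_thresholds])
    ax.set_yticks(range(len(grid.aff_thresholds)),
                  [f"{v:g}" for v in grid.aff_thresholds])
    ax.set_xlabel("similarity threshold")
    ax.set_ylabel("affinity-difference threshold")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
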
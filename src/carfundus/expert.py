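"""Pooled human-expert odds ratios per finding-disease pair, and the
side-by-side comparison of the expert odds-ratio grid with the model's
counterfactual attribution ratio grid.

Every (reader, image) reading contributes one cell to a single 2x2 matrix N
per pair; the odds ratio is N[1,1]*N[0,0] / (N[1,0]*N[0,1]) where the first
index is finding presence and the second disease presence.  Note the matrix
is laid out presence-first: cell (0,0) of the printed matrix corresponds to
finding = 1 and disease = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .car import CARMatrix


@dataclass
class ContingencyTable:
    """2x2 pooled reading counts, ordered (f=1&d=1, f=1&d=0; f=0&d=1, f=0&d=0)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be a 2x2 matrix")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.number):
            raise ValueError("counts must be non-negative numbers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def pooled_contingency(panel: pd.DataFrame, finding: str, disease: str) -> ContingencyTable:
    """Accumulate all (reader, image) readings for one finding-disease pair."""
    for col in (finding, disease):
        if col not in panel.columns:
            raise KeyError(f"label {col!r} not in panel columns")
    f = panel[finding].to_numpy(dtype=int)
    d = panel[disease].to_numpy(dtype=int)
    counts = np.array([
        [int(np.sum((f == 1) & (d == 1))), int(np.sum((f == 1) & (d == 0)))],
        [int(np.sum((f == 0) & (d == 1))), int(np.sum((f == 0) & (d == 0)))],
    ])
    return ContingencyTable(counts)


def odds_ratio(table: ContingencyTable, correction: str = "none") -> float:
    """OR = N11*N00 / (N10*N01) in presence-first layout.

    correction "haldane" adds 0.5 to every cell first (always finite);
    correction "none" returns inf with a warning when the denominator is 0.
    """
    c = table.counts.astype(float)
    if correction == "haldane":
        c = c + 0.5
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    num = c[0, 0] * c[1, 1]
    den = c[0, 1] * c[1, 0]
    if den == 0:
        warnings.warn("zero cell in odds ratio denominator; returning inf "
                      "(use correction='haldane' for a finite value)", stacklevel=2)
        return float("inf")
    return float(num / den)


def expert_or_grid(
    panel: pd.DataFrame,
    findings: list[str],
    diseases: list[str],
    correction: str = "haldane",
) -> pd.DataFrame:
    """F x D grid of pooled expert odds ratios."""
    grid = pd.DataFrame(index=findings, columns=diseases, dtype=float)
    for f in findings:
        for d in diseases:
            grid.loc[f, d] = odds_ratio(pooled_contingency(panel, f, d), correction)
    return grid


def car_or_grid(car: CARMatrix, panel: pd.DataFrame, correction: str = "haldane") -> dict:
    """Pair the model's log-CAR grid with the experts' log-OR grid.

    Returns the two aligned F x D log grids plus a per-disease Spearman rank
    correlation over findings (a scalar summary of the visual agreement
    between the two heatmaps).
    """
    missing = [name for name in (*car.finding_names, *car.disease_names)
               if name not in panel.columns]
    if missing:
        raise KeyError(f"panel is missing labels: {missing}")
    log_or = np.log(expert_or_grid(panel, car.finding_names, car.disease_names, correction))
    log_car = pd.DataFrame(car.log_values(), index=car.finding_names,
                           columns=car.disease_names)
    rank_agreement = {}
    for d in car.disease_names:
        if len(car.finding_names) < 2:
            rank_agreement[d] = float("nan")
            continue
        rho = spearmanr(log_car[d].to_numpy(), log_or[d].to_numpy()).statistic
        rank_agreement[d] = float(rho)
    return {
        "log_car": log_car,
        "log_or": log_or,
        "rank_agreement": pd.Series(rank_agreement, name="spearman_rho"),
    }


def plot_car_or_grids(grids: dict, path: str) -> None:
    """Render the paired heatmaps (model log-CAR vs expert log-OR) to a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    log_car, log_or = grids["log_car"], grids["log_or"]
    vmax = float(np.nanmax(np.abs(np.concatenate([log_car.to_numpy().ravel(),
                                                  log_or.to_numpy().ravel()]))))
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    for ax, grid, title in zip(axes, (log_or, log_car), ("experts: log OR", "model: log CAR")):
        im = ax.imshow(grid.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xticks(range(len(grid.columns)), grid.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(grid.index)), grid.index)
        ax.set_title(title)
    fig.colorbar(im, ax=axes, shrink=0.8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
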
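"""ROC-convex-hull evaluation, Monte-Carlo cross-validation, and
observer-agreement utilities.

Each fitted weighting configuration (or each threshold over the global
score) is an operating point (Sensitivity, Specificity) in ROC space; the
achievable curve is the upper concave envelope — the convex hull — of those
points together with the trivial corners (0,0) and (1,1), and its area
(AUC) summarizes performance. Experiments use repeated random train/test
splits (default 10 repetitions of 80/20) with AUC reported as mean ± sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import SegmentDataset, TortuosityWeightModel

__all__ = [
    "OperatingPoint",
    "ROCHull",
    "CVResult",
    "roc_convex_hull",
    "threshold_sweep",
    "monte_carlo_cv",
    "cohen_kappa",
]


@dataclass(frozen=True)
class OperatingPoint:
    """A (Sensitivity, Specificity) pair with optional provenance."""

    sensitivity: float
    specificity: float
    provenance: str | float | int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.specificity <= 1):
            raise ValueError("Sen and Sp must lie in [0, 1]")

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity

    @property
    def tpr(self) -> float:
        return self.sensitivity


@dataclass
class ROCHull:
    """Upper concave envelope of operating points in (FPR, TPR) space."""

    vertices: np.ndarray  # (k, 2) sorted by FPR, includes (0,0) and (1,1)
    auc: float

    def interpolate(self, fpr_grid: np.ndarray) -> np.ndarray:
        """TPR of the hull at given FPR values (piecewise linear)."""
        return np.interp(fpr_grid, self.vertices[:, 0], self.vertices[:, 1])


def roc_convex_hull(points: list[OperatingPoint]) -> ROCHull:
    """Convex hull ROC curve of a set of operating points.

    The hull always contains the trivial classifiers (0,0) and (1,1); AUC is
    the exact trapezoid sum over the hull vertices.
    """
    if not points:
        raise ValueError("at least one operating point required")
    pts = np.array([[p.fpr, p.tpr] for p in points] + [[0.0, 0.0], [1.0, 1.0]])
    pts = np.unique(pts, axis=0)  # sorted by fpr then tpr
    # Andrew monotone chain, upper envelope (keep right turns / concavity)
    hull: list[np.ndarray] = []
    for p in pts:
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0])
            if cross >= 0:  # 'a' lies on or below chord o-p: not on upper hull
                hull.pop()
            else:
                break
        hull.append(p)
    vertices = np.asarray(hull)
    auc = float(np.trapezoid(vertices[:, 1], vertices[:, 0]))
    return ROCHull(vertices=vertices, auc=auc)


def threshold_sweep(scores: list[tuple[float, int]]) -> list[OperatingPoint]:
    """Operating points from sweeping thresholds over global scores.

    Thresholds are the midpoints between consecutive distinct scores plus
    one below the minimum and one above the maximum, so every achievable
    confusion table appears exactly once.
    """
    s = np.asarray([x[0] for x in scores], dtype=float)
    y = np.asarray([x[1] for x in scores], dtype=int)
    if len(s) == 0 or y.min() == y.max():
        raise ValueError("scores must contain both classes")
    uniq = np.unique(s)
    thresholds = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    pos = y == 1
    neg = ~pos
    points = []
    for t in thresholds:
        pred = s > t
        sen = float(pred[pos].mean())
        sp = float((~pred)[neg].mean())
        points.append(OperatingPoint(sen, sp, provenance=float(t)))
    return points


@dataclass
class CVResult:
    """Per-split hull AUCs of a Monte-Carlo cross-validation."""

    aucs: list[float]
    seeds: list[int]
    mean_curve_fpr: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 101))
    mean_curve_tpr: np.ndarray | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def std(self) -> float:
        return float(np.std(self.aucs))

    def __repr__(self) -> str:
        return f"CVResult(AUC = {self.mean:.4f} ± {self.std:.4f}, n={len(self.aucs)})"


def _stratified_split(labels: np.ndarray, train_frac: float, rng: np.random.Generator):
    n = len(labels)
    idx = np.arange(n)
    train_idx: list[int] = []
    for cls in np.unique(labels):
        members = idx[labels == cls]
        members = rng.permutation(members)
        k = max(int(round(train_frac * len(members))), 1)
        k = min(k, len(members) - 1)  # keep at least one test member per class
        train_idx.extend(members[:k].tolist())
    train = np.asarray(sorted(train_idx), dtype=int)
    test = np.asarray(sorted(set(idx.tolist()) - set(train_idx)), dtype=int)
    return train, test


def monte_carlo_cv(
    tables: list[pd.DataFrame],
    labels: list[int],
    mode: str = "fit",
    n_repeats: int = 10,
    train_frac: float = 0.8,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> CVResult:
    """Repeated random-split evaluation with hull AUC per split.

    ``mode="fit"`` runs the NSGA-II weighting fit on each training split and
    measures the front's operating points on the test split; ``mode="sweep"``
    skips fitting and sweeps thresholds over length-weighted scores on the
    test split. Splits are stratified by label so Sen and Sp stay defined.
    Reported AUC is the mean ± sd of per-split hull AUCs; a vertically
    averaged hull curve on a fixed FPR grid is also provided.
    """
    labels_arr = np.asarray(labels, dtype=int)
    if len(tables) < 10:
        raise ValueError("dataset too small for Monte-Carlo cross-validation")
    if labels_arr.min() == labels_arr.max():
        raise ValueError("dataset must contain both classes")
    rng = np.random.default_rng(seed)
    fit_kwargs = dict(fit_kwargs or {})
    grid = np.linspace(0, 1, 101)
    aucs, seeds, curves = [], [], []
    for rep in range(n_repeats):
        split_seed = int(rng.integers(0, 2**31 - 1))
        split_rng = np.random.default_rng(split_seed)
        train, test = _stratified_split(labels_arr, train_frac, split_rng)
        test_tables = [tables[i] for i in test]
        test_labels = labels_arr[test].tolist()
        if mode == "fit":
            model = TortuosityWeightModel.from_tables(
                [tables[i] for i in train], labels_arr[train].tolist()
            )
            res = model.fit(seed=split_seed % (2**31 - 1), **fit_kwargs)
            ops = res.operating_points(test_tables, test_labels)
            points = [
                OperatingPoint(r.sensitivity, r.specificity)
                for r in ops.itertuples()
            ]
        elif mode == "sweep":
            ds = SegmentDataset(test_tables)
            zero = np.zeros((1, 5))  # length-only weighting
            scores = ds.scores(zero)[0]
            points = threshold_sweep(list(zip(scores.tolist(), test_labels)))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        hull = roc_convex_hull(points)
        aucs.append(hull.auc)
        seeds.append(split_seed)
        curves.append(hull.interpolate(grid))
    return CVResult(
        aucs=aucs,
        seeds=seeds,
        mean_curve_fpr=grid,
        mean_curve_tpr=np.mean(curves, axis=0),
    )


def cohen_kappa(a, b) -> float:
    """Chance-corrected agreement between two binary label lists.

    kappa = (p_o - p_e) / (1 - p_e); by convention identical lists return
    1.0 even when the chance agreement is also 1.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("inputs must be equal-length non-empty 1-D label lists")
    p_o = float((a == b).mean())
    p_e = 0.0
    n = len(a)
    for cls in np.union1d(a, b):
        p_e += float((a == cls).sum()) / n * float((b == cls).sum()) / n
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))
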
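"""Fitting the weighting coefficients and decision threshold by NSGA-II.

The five genes (omega_AV, omega_Cal, omega_dOD, omega_dFov, phi_tort) are
optimized to jointly maximize Sensitivity and Specificity of the binary
tortuosity classification over a labeled set of images. NSGA-II evolves a
population with simulated binary crossover (eta_c=15, p_c=0.9) and
polynomial mutation (eta_m=20, p_m=0.9), merges parents and offspring each
generation (elitism), and ranks survivors by non-dominated front then
crowding distance; binary tournaments use the same criteria. The result is
the final Pareto front of (Sen, Sp) trade-offs.

The front door is :class:`TortuosityWeightModel`, whose ``fit`` returns a
:class:`TortuosityFitResults` carrying the front, the balanced-accuracy
optimum, and a ``summary()`` table; the individual operators are exposed so
they can be verified against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .score import ImageAssessment, WeightConfig

__all__ = [
    "GeneBounds",
    "SegmentDataset",
    "EvaluatedIndividual",
    "evaluate_genome",
    "nondominated_sort",
    "crowding_distance",
    "sbx_crossover",
    "polynomial_mutation",
    "run_nsga2",
    "TortuosityWeightModel",
    "TortuosityFitResults",
]

_GENE_NAMES = ["omega_av", "omega_cal", "omega_dod", "omega_dfov", "phi_tort"]


@dataclass(frozen=True)
class GeneBounds:
    """Box bounds of the 5-gene genome.

    omega_AV is bounded in [0, 1] by construction; the remaining
    coefficients are non-negative with configurable uppers sized so that the
    pixel-unit terms (calibers ~4-16 px, distances up to ~600 px) can range
    from dominant to negligible in the weighting factor.
    """

    omega_cal_max: float = 1.0
    omega_dod_max: float = 0.1
    omega_dfov_max: float = 0.1
    phi_tort_max: float = 0.1

    @property
    def lower(self) -> np.ndarray:
        return np.zeros(5)

    @property
    def upper(self) -> np.ndarray:
        return np.array(
            [1.0, self.omega_cal_max, self.omega_dod_max, self.omega_dfov_max, self.phi_tort_max]
        )


class SegmentDataset:
    """Labeled per-image segment tables flattened for fast genome evaluation.

    Stores one row per segment (length, factors, tortuosity) with an image
    index, plus per-image binary labels; a whole population of genomes is
    evaluated with a few matrix products.
    """

    def __init__(self, tables: list[pd.DataFrame], labels: list[int] | None = None):
        if len(tables) == 0:
            raise ValueError("empty dataset")
        if labels is not None:
            if len(tables) != len(labels):
                raise ValueError("one label per image required")
            self.labels = np.asarray(labels, dtype=int)
            if self.labels.min() == self.labels.max():
                raise ValueError("dataset must contain both classes")
        else:
            self.labels = None
        rows = []
        img_idx = []
        for i, df in enumerate(tables):
            rows.append(df[["L_c", "f_av", "f_cal", "f_dod", "f_dfov", "tortuosity"]])
            img_idx.extend([i] * len(df))
        flat = pd.concat(rows, ignore_index=True)
        self.L = flat["L_c"].to_numpy(dtype=float)
        self.f_av = flat["f_av"].to_numpy(dtype=float)
        self.f_cal = flat["f_cal"].to_numpy(dtype=float)
        self.f_dod = flat["f_dod"].to_numpy(dtype=float)
        self.f_dfov = flat["f_dfov"].to_numpy(dtype=float)
        self.tau = flat["tortuosity"].to_numpy(dtype=float)
        self.n_images = len(tables)
        # indicator matrix (images x segments) for per-image aggregation
        self._M = np.zeros((self.n_images, len(flat)))
        self._M[np.asarray(img_idx, dtype=int), np.arange(len(flat))] = 1.0

    @classmethod
    def from_assessments(
        cls, assessments: list[ImageAssessment], labels: list[int]
    ) -> "SegmentDataset":
        return cls([a.segments for a in assessments], labels)

    @classmethod
    def from_ground_truth(cls, ground_truths, labels=None) -> "SegmentDataset":
        """Build from synthetic scene ground truth (analytic factors)."""
        tables = []
        got_labels = []
        for gt in ground_truths:
            df = pd.DataFrame(
                {
                    "L_c": gt.vessels["arc_length"].round().clip(lower=1),
                    "f_av": (gt.vessels["vessel_class"] == "artery").astype(float),
                    "f_cal": gt.vessels["caliber"],
                    "f_dod": gt.vessels["d_od"],
                    "f_dfov": gt.vessels["d_fov"],
                    "tortuosity": gt.vessels["tortuosity"],
                }
            )
            tables.append(df)
            got_labels.append(gt.label)
        return cls(tables, list(labels) if labels is not None else got_labels)

    def scores(self, genomes: np.ndarray) -> np.ndarray:
        """Global tortuosity scores, shape (n_genomes, n_images)."""
        W = np.atleast_2d(np.asarray(genomes, dtype=float))
        w_av, w_cal, w_dod, w_dfov = W[:, 0:1], W[:, 1:2], W[:, 2:3], W[:, 3:4]
        bracket = w_av * self.f_av[None, :] + (1 - w_av) * (1 - self.f_av[None, :])
        F = self.L[None, :] * (
            bracket
            + w_cal * self.f_cal[None, :]
            + w_dod * self.f_dod[None, :]
            + w_dfov * self.f_dfov[None, :]
        )
        denom = F @ self._M.T
        numer = (F * self.tau[None, :]) @ self._M.T
        with np.errstate(invalid="ignore", divide="ignore"):
            tau_f = np.where(denom > 0, numer / denom, 0.0)
        return tau_f

    def evaluate(self, genomes: np.ndarray) -> np.ndarray:
        """(Sensitivity, Specificity) per genome, shape (n_genomes, 2)."""
        if self.labels is None:
            raise ValueError("dataset has no labels; Sen/Sp undefined")
        W = np.atleast_2d(np.asarray(genomes, dtype=float))
        tau_f = self.scores(W)
        pred = tau_f > W[:, 4:5]
        pos = self.labels == 1
        neg = ~pos
        sen = pred[:, pos].mean(axis=1)
        sp = (~pred)[:, neg].mean(axis=1)
        return np.column_stack([sen, sp])


def evaluate_genome(genome: np.ndarray, dataset: SegmentDataset) -> tuple[float, float]:
    """Sensitivity and Specificity of one genome over the dataset."""
    sen, sp = dataset.evaluate(np.asarray(genome)[None, :])[0]
    return float(sen), float(sp)


# ---------------------------------------------------------------------------
# NSGA-II operators (objectives are maximized)
# ---------------------------------------------------------------------------


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a >= b) and np.any(a > b))


def nondominated_sort(objectives: np.ndarray) -> list[np.ndarray]:
    """Partition a population into non-dominated fronts (maximization).

    Front 1 holds individuals dominated by nobody; each later front is
    dominated only by members of earlier fronts.
    """
    obj = np.asarray(objectives, dtype=float)
    n = len(obj)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(obj[i], obj[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif _dominates(obj[j], obj[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = []
    current = np.nonzero(dom_count == 0)[0]
    while current.size:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        current = np.asarray(sorted(nxt), dtype=int)
    return fronts


def crowding_distance(objectives: np.ndarray) -> np.ndarray:
    """Crowding distance of each member of one front.

    Boundary solutions of each objective get infinity; interior solutions
    accumulate the normalized gap between their neighbors in each objective.
    """
    obj = np.atleast_2d(np.asarray(objectives, dtype=float))
    n, m = obj.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(obj[:, k], kind="stable")
        lo, hi = obj[order[0], k], obj[order[-1], k]
        dist[order[0]] = dist[order[-1]] = np.inf
        rng = hi - lo
        if rng <= 0:
            continue
        gaps = (obj[order[2:], k] - obj[order[:-2], k]) / rng
        dist[order[1:-1]] += gaps
    return dist


def sbx_crossover(
    p1: np.ndarray,
    p2: np.ndarray,
    bounds: GeneBounds,
    rng: np.random.Generator,
    eta_c: float = 15.0,
    p_c: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover (bounded, Deb & Agrawal).

    With probability ``1 - p_c`` the parents are copied unchanged. Each gene
    recombines with probability 0.5; the spread factor is drawn so that the
    offspring mean equals the parent midpoint and both children respect the
    box bounds.
    """
    lo, hi = bounds.lower, bounds.upper
    c1, c2 = p1.astype(float).copy(), p2.astype(float).copy()
    if rng.random() > p_c:
        return c1, c2
    for k in range(len(c1)):
        if rng.random() > 0.5:
            continue
        x1, x2 = c1[k], c2[k]
        if abs(x1 - x2) < 1e-14:
            continue
        y1, y2 = min(x1, x2), max(x1, x2)
        u = rng.random()
        # boundary-aware spread factors
        beta = 1.0 + 2.0 * (y1 - lo[k]) / (y2 - y1)
        alpha = 2.0 - beta ** -(eta_c + 1.0)
        if u <= 1.0 / alpha:
            beta_q = (u * alpha) ** (1.0 / (eta_c + 1.0))
        else:
            beta_q = (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta_c + 1.0))
        child1 = 0.5 * ((y1 + y2) - beta_q * (y2 - y1))
        beta = 1.0 + 2.0 * (hi[k] - y2) / (y2 - y1)
        alpha = 2.0 - beta ** -(eta_c + 1.0)
        if u <= 1.0 / alpha:
            beta_q = (u * alpha) ** (1.0 / (eta_c + 1.0))
        else:
            beta_q = (1.0 / (2.0 - u * alpha)) ** (1.0 / (eta_c + 1.0))
        child2 = 0.5 * ((y1 + y2) + beta_q * (y2 - y1))
        child1 = float(np.clip(child1, lo[k], hi[k]))
        child2 = float(np.clip(child2, lo[k], hi[k]))
        if rng.random() < 0.5:
            child1, child2 = child2, child1
        c1[k], c2[k] = child1, child2
    return c1, c2


def polynomial_mutation(
    genome: np.ndarray,
    bounds: GeneBounds,
    rng: np.random.Generator,
    eta_m: float = 20.0,
    p_m: float = 0.9,
    per_gene_rate: float | None = None,
) -> np.ndarray:
    """Bounded polynomial mutation (Deb).

    ``p_m`` is the per-genome probability that mutation is attempted at all;
    inside, each gene mutates with the conventional rate ``1 / n_genes``
    unless ``per_gene_rate`` overrides it. Perturbations are symmetric about
    the current value away from the bounds and shrink towards them.
    """
    lo, hi = bounds.lower, bounds.upper
    g = genome.astype(float).copy()
    if rng.random() > p_m:
        return g
    rate = per_gene_rate if per_gene_rate is not None else 1.0 / len(g)
    for k in range(len(g)):
        if rng.random() > rate:
            continue
        span = hi[k] - lo[k]
        if span <= 0:
            continue
        x = g[k]
        d1 = (x - lo[k]) / span
        d2 = (hi[k] - x) / span
        u = rng.random()
        mut_pow = 1.0 / (eta_m + 1.0)
        if u < 0.5:
            xy = 1.0 - d1
            val = 2.0 * u + (1.0 - 2.0 * u) * xy ** (eta_m + 1.0)
            delta = val**mut_pow - 1.0
        else:
            xy = 1.0 - d2
            val = 2.0 * (1.0 - u) + 2.0 * (u - 0.5) * xy ** (eta_m + 1.0)
            delta = 1.0 - val**mut_pow
        g[k] = float(np.clip(x + delta * span, lo[k], hi[k]))
    return g


@dataclass
class EvaluatedIndividual:
    """A genome with its objectives, front rank, and crowding distance."""

    genome: np.ndarray
    sensitivity: float
    specificity: float
    rank: int = 1
    crowding: float = np.inf

    @property
    def weights(self) -> WeightConfig:
        return WeightConfig.from_genome(self.genome)


def _rank_and_crowd(objectives: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    fronts = nondominated_sort(objectives)
    rank = np.zeros(len(objectives), dtype=int)
    crowd = np.zeros(len(objectives))
    for fi, front in enumerate(fronts, start=1):
        rank[front] = fi
        crowd[front] = crowding_distance(objectives[front])
    return rank, crowd


def _tournament(rank, crowd, rng) -> int:
    i, j = rng.integers(0, len(rank), size=2)
    if rank[i] < rank[j]:
        return int(i)
    if rank[j] < rank[i]:
        return int(j)
    if crowd[i] > crowd[j]:
        return int(i)
    if crowd[j] > crowd[i]:
        return int(j)
    return int(i)


def run_nsga2(
    dataset: SegmentDataset,
    pop_size: int = 100,
    seed: int = 0,
    max_generations: int = 200,
    stall_generations: int = 25,
    bounds: GeneBounds = GeneBounds(),
    eta_c: float = 15.0,
    p_c: float = 0.9,
    eta_m: float = 20.0,
    p_m: float = 0.9,
) -> tuple[list[EvaluatedIndividual], dict]:
    """Evolve weighting coefficients and threshold; return the Pareto front.

    Elitist mu+lambda survival over merged parent and offspring populations;
    the run stops when the first front's objective set has not changed for
    ``stall_generations`` generations, or at ``max_generations``. Fully
    deterministic for a given seed.
    """
    if pop_size % 2:
        raise ValueError("pop_size must be even")
    rng = np.random.default_rng(seed)
    lo, hi = bounds.lower, bounds.upper
    pop = lo + rng.random((pop_size, 5)) * (hi - lo)
    obj = dataset.evaluate(pop)
    rank, crowd = _rank_and_crowd(obj)

    front_signature = None
    stall = 0
    generations = 0
    reason = "max_generations"
    for gen in range(1, max_generations + 1):
        generations = gen
        # offspring by tournament selection, SBX, polynomial mutation
        children = np.empty_like(pop)
        for k in range(0, pop_size, 2):
            a = pop[_tournament(rank, crowd, rng)]
            b = pop[_tournament(rank, crowd, rng)]
            c1, c2 = sbx_crossover(a, b, bounds, rng, eta_c=eta_c, p_c=p_c)
            children[k] = polynomial_mutation(c1, bounds, rng, eta_m=eta_m, p_m=p_m)
            children[k + 1] = polynomial_mutation(c2, bounds, rng, eta_m=eta_m, p_m=p_m)
        child_obj = dataset.evaluate(children)
        merged = np.vstack([pop, children])
        merged_obj = np.vstack([obj, child_obj])
        fronts = nondominated_sort(merged_obj)
        # mu+lambda survival: fill by front, last front by crowding
        keep: list[int] = []
        for front in fronts:
            if len(keep) + len(front) <= pop_size:
                keep.extend(front.tolist())
            else:
                cd = crowding_distance(merged_obj[front])
                order = np.argsort(-cd, kind="stable")
                keep.extend(front[order][: pop_size - len(keep)].tolist())
                break
        keep_idx = np.asarray(keep, dtype=int)
        pop = merged[keep_idx]
        obj = merged_obj[keep_idx]
        rank, crowd = _rank_and_crowd(obj)

        sig = tuple(sorted(map(tuple, np.round(obj[rank == 1], 12))))
        if sig == front_signature:
            stall += 1
            if stall >= stall_generations:
                reason = "stalled"
                break
        else:
            front_signature = sig
            stall = 0

    first = np.nonzero(rank == 1)[0]
    # deduplicate genomes on the front
    seen = set()
    front_members: list[EvaluatedIndividual] = []
    for i in first:
        key = tuple(np.round(pop[i], 12))
        if key in seen:
            continue
        seen.add(key)
        front_members.append(
            EvaluatedIndividual(
                genome=pop[i].copy(),
                sensitivity=float(obj[i, 0]),
                specificity=float(obj[i, 1]),
                rank=1,
                crowding=float(crowd[i]),
            )
        )
    info = {"generations": generations, "stopping_reason": reason, "seed": seed}
    return front_members, info


# ---------------------------------------------------------------------------
# model / results front-end
# ---------------------------------------------------------------------------


class TortuosityWeightModel:
    """Weighting-coefficient model over a labeled set of assessed images.

    Built from per-image segment tables (measured by the pipeline or taken
    from synthetic ground truth) and binary tortuosity labels; ``fit``
    optimizes (omega_AV, omega_Cal, omega_dOD, omega_dFov, phi_tort) by
    NSGA-II and returns a results object with the Pareto front.
    """

    def __init__(self, dataset: SegmentDataset):
        self.dataset = dataset

    @classmethod
    def from_assessments(cls, assessments, labels) -> "TortuosityWeightModel":
        return cls(SegmentDataset.from_assessments(list(assessments), list(labels)))

    @classmethod
    def from_tables(cls, tables, labels) -> "TortuosityWeightModel":
        return cls(SegmentDataset(list(tables), list(labels)))

    def fit(
        self,
        pop_size: int = 100,
        seed: int = 0,
        max_generations: int = 200,
        stall_generations: int = 25,
        bounds: GeneBounds = GeneBounds(),
    ) -> "TortuosityFitResults":
        front, info = run_nsga2(
            self.dataset,
            pop_size=pop_size,
            seed=seed,
            max_generations=max_generations,
            stall_generations=stall_generations,
            bounds=bounds,
        )
        return TortuosityFitResults(model=self, front=front, info=info)


@dataclass
class TortuosityFitResults:
    """Pareto front of fitted weighting configurations.

    ``best`` selects the front member with the highest balanced accuracy
    (Sen + Sp) / 2 on the training data; ``predict`` applies any member to
    new segment tables.
    """

    model: TortuosityWeightModel
    front: list[EvaluatedIndividual]
    info: dict = field(default_factory=dict)

    @property
    def front_table(self) -> pd.DataFrame:
        rows = []
        for ind in self.front:
            row = dict(zip(_GENE_NAMES, ind.genome))
            row["sensitivity"] = ind.sensitivity
            row["specificity"] = ind.specificity
            row["balanced_accuracy"] = (ind.sensitivity + ind.specificity) / 2
            rows.append(row)
        return (
            pd.DataFrame(rows)
            .sort_values("balanced_accuracy", ascending=False)
            .reset_index(drop=True)
        )

    @property
    def best(self) -> EvaluatedIndividual:
        return max(self.front, key=lambda i: (i.sensitivity + i.specificity, -i.genome[4]))

    def predict(self, tables) -> np.ndarray:
        """Binary predictions of the best front member on new images."""
        ds = SegmentDataset(list(tables))
        scores = ds.scores(self.best.genome[None, :])[0]
        return (scores > self.best.genome[4]).astype(int)

    def operating_points(self, tables=None, labels=None) -> pd.DataFrame:
        """(Sen, Sp) of every front member, optionally on held-out data."""
        if tables is None:
            ds = self.model.dataset
        else:
            ds = SegmentDataset(list(tables), list(labels))
        genomes = np.vstack([ind.genome for ind in self.front])
        obj = ds.evaluate(genomes)
        out = pd.DataFrame(genomes, columns=_GENE_NAMES)
        out["sensitivity"] = obj[:, 0]
        out["specificity"] = obj[:, 1]
        return out

    def summary(self) -> str:
        best = self.best
        lines = [
            "Tortuosity weighting fit (NSGA-II)",
            "=" * 50,
            f"images: {self.model.dataset.n_images}"
            f"   positives: {int(self.model.dataset.labels.sum())}",
            f"generations: {self.info.get('generations', '?')}"
            f"   stop: {self.info.get('stopping_reason', '?')}"
            f"   seed: {self.info.get('seed', '?')}",
            f"Pareto front size: {len(self.front)}",
            "",
            "best balanced-accuracy member:",
        ]
        for name, value in zip(_GENE_NAMES, best.genome):
            lines.append(f"  {name:<12} {value: .6g}")
        lines.append(
            f"  Sen {best.sensitivity:.3f}   Sp {best.specificity:.3f}   "
            f"bAcc {(best.sensitivity + best.specificity) / 2:.3f}"
        )
        return "\n".join(lines)
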
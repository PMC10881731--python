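"""Image-level tortuosity: anatomically weighted aggregation of per-segment
values and binary classification against a threshold.

The global score is the weighted mean

    tau_f = sum_i tau_vi * f_i / sum_i f_i

with per-segment weighting factor

    f_i = L_ci * [ (w_AV * f_AV + (1 - w_AV) * (1 - f_AV))
                   + w_Cal * f_Cal + w_dOD * f_dOD + w_dFov * f_dFov ]

where ``L_ci`` is the segment length in pixels and the anatomical factors
are in raw pixel units (no normalization), so the fitted coefficient
magnitudes are scale-bearing. Without anatomical factors the standard
length weighting ``f_i = L_ci`` is used. An image is classified as tortuous
when ``tau_f`` is strictly greater than the threshold ``phi_tort``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .factors import SegmentFactors, reversed_od_distance

__all__ = [
    "WeightConfig",
    "ImageAssessment",
    "UnscorableImageError",
    "segment_weight",
    "global_tortuosity",
    "classify",
]


class UnscorableImageError(ValueError):
    """No segments with positive weight: the image cannot be scored."""


@dataclass(frozen=True)
class WeightConfig:
    """Coefficients of the weighting factor and the decision threshold.

    ``omega_av`` lies in [0, 1] (its complement weights veins); the other
    coefficients are non-negative and multiply pixel-unit factors, which is
    why fitted values for distance terms are typically small (1e-3-ish).
    Mode flags disable individual factors; with every factor disabled the
    weight reduces to the plain segment length. ``reversed_dod`` substitutes
    ``Rd_OD = k_od - d_OD`` for the optic-disc distance.
    """

    omega_av: float = 0.0
    omega_cal: float = 0.0
    omega_dod: float = 0.0
    omega_dfov: float = 0.0
    phi_tort: float = 0.0
    use_av: bool = True
    use_cal: bool = True
    use_dod: bool = True
    use_dfov: bool = True
    reversed_dod: bool = False
    k_od: float = 600.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega_av <= 1.0:
            raise ValueError("omega_av must lie in [0, 1]")
        for name in ("omega_cal", "omega_dod", "omega_dfov", "phi_tort"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def length_only(cls, phi_tort: float = 0.0) -> "WeightConfig":
        """Standard length weighting: every anatomical factor disabled."""
        return cls(
            phi_tort=phi_tort,
            use_av=False,
            use_cal=False,
            use_dod=False,
            use_dfov=False,
        )

    @classmethod
    def reference_fitted(cls) -> "WeightConfig":
        """A representative fitted configuration (balanced-accuracy optimum
        of a model trained on clinical data), useful as a plausible default."""
        return cls(
            omega_av=2.23e-1,
            omega_cal=8.83e-2,
            omega_dod=1.32e-3,
            omega_dfov=6.51e-4,
            phi_tort=2.46e-3,
        )

    def with_threshold(self, phi_tort: float) -> "WeightConfig":
        return replace(self, phi_tort=phi_tort)

    def as_genome(self) -> np.ndarray:
        return np.array(
            [self.omega_av, self.omega_cal, self.omega_dod, self.omega_dfov, self.phi_tort]
        )

    @classmethod
    def from_genome(cls, genome: np.ndarray, **flags) -> "WeightConfig":
        g = np.asarray(genome, dtype=float)
        return cls(
            omega_av=float(g[0]),
            omega_cal=float(g[1]),
            omega_dod=float(g[2]),
            omega_dfov=float(g[3]),
            phi_tort=float(g[4]),
            **flags,
        )


def segment_weight(factors: SegmentFactors, w: WeightConfig) -> float:
    """Weighting factor ``f_i`` of one segment under a configuration.

    Disabled terms contribute 0; when the artery/vein term is disabled the
    convex bracket is replaced by 1 so that single-factor configurations
    stay well defined.
    """
    bracket = 1.0
    if w.use_av:
        if factors.f_av is None:
            raise ValueError("f_av required but missing")
        bracket = w.omega_av * factors.f_av + (1.0 - w.omega_av) * (1.0 - factors.f_av)
    terms = bracket
    if w.use_cal:
        terms += w.omega_cal * factors.f_cal
    if w.use_dod:
        d = factors.f_dod
        if w.reversed_dod:
            d = reversed_od_distance(d, k=w.k_od)
        terms += w.omega_dod * d
    if w.use_dfov:
        terms += w.omega_dfov * factors.f_dfov
    return float(factors.L_c * terms)


def global_tortuosity(segments: list[tuple[float, float]]) -> float:
    """Weighted mean of per-segment tortuosity values.

    ``segments`` is a list of ``(tau_v, f_i)`` pairs. Raises
    :class:`UnscorableImageError` when there are no segments or the weights
    sum to zero.
    """
    if not segments:
        raise UnscorableImageError("image has no vessel segments to score")
    tau = np.asarray([s[0] for s in segments], dtype=float)
    f = np.asarray([s[1] for s in segments], dtype=float)
    total = f.sum()
    if total <= 0:
        raise UnscorableImageError("all segment weights are zero")
    return float(np.dot(tau, f) / total)


def classify(tau_f: float, phi_tort: float) -> int:
    """1 (tortuous) iff the global score strictly exceeds the threshold."""
    if phi_tort < 0:
        raise ValueError("phi_tort must be non-negative")
    return int(tau_f > phi_tort)


@dataclass
class ImageAssessment:
    """Full per-image result: segment table, global score, and label.

    ``segments`` holds one row per vessel segment with its pixel path id,
    measured factors, tortuosity ``tau_v``, weighting factor ``f_i`` and net
    contribution ``tau_v * f_i / sum f`` (contributions sum to ``tau_f``).
    """

    segments: pd.DataFrame
    weights: WeightConfig
    tau_f: float
    label: int
    paths: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def from_measurements(
        cls,
        factor_list: list[SegmentFactors],
        tortuosities: list[float],
        weights: WeightConfig,
        paths: list[np.ndarray] | None = None,
        trees: list[str] | None = None,
    ) -> "ImageAssessment":
        if len(factor_list) != len(tortuosities):
            raise ValueError("factor and tortuosity counts differ")
        f_i = [segment_weight(fa, weights) for fa in factor_list]
        tau_f = global_tortuosity(list(zip(tortuosities, f_i)))
        total = sum(f_i)
        df = pd.DataFrame(
            {
                "segment_id": np.arange(len(factor_list)),
                "tree": trees if trees is not None else [""] * len(factor_list),
                "L_c": [fa.L_c for fa in factor_list],
                "f_cal": [fa.f_cal for fa in factor_list],
                "f_av": [fa.f_av for fa in factor_list],
                "assigned_class": [fa.assigned_class for fa in factor_list],
                "f_dod": [fa.f_dod for fa in factor_list],
                "f_dfov": [fa.f_dfov for fa in factor_list],
                "tortuosity": tortuosities,
                "f_i": f_i,
                "contribution": [t * f / total for t, f in zip(tortuosities, f_i)],
            }
        )
        return cls(
            segments=df,
            weights=weights,
            tau_f=tau_f,
            label=classify(tau_f, weights.phi_tort),
            paths=paths or [],
        )

    def rescore(self, weights: WeightConfig) -> "ImageAssessment":
        """Recompute weights, score, and label under a new configuration."""
        factor_list = [
            SegmentFactors(
                L_c=int(row.L_c),
                f_cal=row.f_cal,
                f_av=row.f_av,
                f_dod=row.f_dod,
                f_dfov=row.f_dfov,
                assigned_class=row.assigned_class,
            )
            for row in self.segments.itertuples()
        ]
        return ImageAssessment.from_measurements(
            factor_list,
            list(self.segments["tortuosity"]),
            weights,
            paths=self.paths,
            trees=list(self.segments["tree"]),
        )

    def to_json_dict(self) -> dict:
        return {
            "tau_f": self.tau_f,
            "label": self.label,
            "weights": {
                "omega_av": self.weights.omega_av,
                "omega_cal": self.weights.omega_cal,
                "omega_dod": self.weights.omega_dod,
                "omega_dfov": self.weights.omega_dfov,
                "phi_tort": self.weights.phi_tort,
            },
            "segments": self.segments.drop(columns=["tree"]).to_dict("records"),
        }
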
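"""Indicator normalization and the radar-area soil health index (SHI).

Normalization
-------------
Each MDS indicator is summarized as its treatment mean ``Pi`` and scored
against a reference ``P`` as ``stPi = Pi / P``:

* ``more_is_better`` — P is the maximum treatment mean, so the best
  treatment scores 1 (a documented convention, symmetric with the minimum
  rule below).
* ``less_is_better`` — P is the minimum treatment mean. In the literal
  mode this gives stPi = Pi/P_min >= 1 (worse soils score *higher*, which
  inflates the index); the ``ratio_inverted`` mode scores P_min/Pi instead,
  keeping every score in (0, 1].
* ``optimum`` — P is the target value; ``ratio_inverted`` mode scores
  min(Pi/T, T/Pi) so over- and undershooting both lose score.

Index
-----
With n selected indicators and scores stP1..stPn placed on radar spokes,

    SHI = 0.5 * sum_i stPi^2 * sin(2*pi/n)          (squared form, default)
    SHI = 0.5 * sin(2*pi/n) * sum_i stPi * stP_{i+1}  (polygon form, cyclic)

The squared form treats each score as its own spoke triangle and is
order-independent; the polygon form is the true enclosed radar-polygon
area and depends on spoke order (here: descending network centrality).
Both are degree-2 homogeneous in the scores and coincide when all scores
are equal. The circle constant defaults to 3.14 (the rounded value used in
the index definition); pass ``pi_constant=math.pi`` for the exact one.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, GeometryError, NormalizationError
from .indicators import IndicatorMeta, IndicatorTable

NORMALIZATION_MODES = ("literal_ratio", "ratio_inverted")
FORMULA_VARIANTS = ("squared_sum", "polygon_product")


@dataclass(frozen=True)
class SHIConfig:
    pi_constant: float = 3.14
    formula_variant: str = "squared_sum"
    normalization_mode: str = "literal_ratio"

    def __post_init__(self) -> None:
        if self.pi_constant <= 0:
            raise ConfigurationError(f"pi_constant must be > 0, got {self.pi_constant}")
        if self.formula_variant not in FORMULA_VARIANTS:
            raise ConfigurationError(
                f"formula_variant must be one of {FORMULA_VARIANTS}, "
                f"got {self.formula_variant!r}"
            )
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ConfigurationError(
                f"normalization_mode must be one of {NORMALIZATION_MODES}, "
                f"got {self.normalization_mode!r}"
            )


@dataclass
class NormalizedScores:
    """Per-treatment stPi scores for each MDS indicator."""

    scores: pd.DataFrame  # treatments × indicators
    references: pd.Series  # indicator -> P
    mode: str

    @property
    def indicators(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def treatments(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class SHIResult:
    shi: pd.Series  # treatment -> index value
    percent_change: pd.Series  # treatment -> % change vs control
    control: str
    vertices: dict[str, list[tuple[float, float]]]  # radar polygon per treatment
    config: SHIConfig
    indicator_order: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "control": self.control,
            "indicator_order": self.indicator_order,
            "shi": {k: float(v) for k, v in self.shi.items()},
            "percent_change_vs_control": {
                k: float(v) for k, v in self.percent_change.items()
            },
            "pi_constant": self.config.pi_constant,
            "formula_variant": self.config.formula_variant,
            "normalization_mode": self.config.normalization_mode,
            "vertices": {
                t: [[float(x), float(y)] for x, y in pts]
                for t, pts in self.vertices.items()
            },
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def normalize_indicators(
    table: IndicatorTable,
    mds: Sequence[str],
    meta: Mapping[str, IndicatorMeta] | None = None,
    mode: str = "literal_ratio",
) -> NormalizedScores:
    """Score each MDS indicator's treatment means against its reference."""
    if mode not in NORMALIZATION_MODES:
        raise ConfigurationError(
            f"mode must be one of {NORMALIZATION_MODES}, got {mode!r}"
        )
    meta = dict(meta or {})
    meta = {**{name: IndicatorMeta() for name in mds}, **table.meta, **meta}
    missing = [m for m in mds if m not in table.indicator_names]
    if missing:
        raise NormalizationError(f"MDS indicator(s) not in table: {missing}")

    means = table.treatment_means()[list(mds)]
    bad = means[means <= 0].stack()
    if not bad.empty:
        trt, ind = bad.index[0]
        raise NormalizationError(
            f"non-positive treatment mean for indicator {ind!r}, treatment {trt!r}"
        )

    scores = pd.DataFrame(index=means.index, columns=list(mds), dtype=float)
    refs = pd.Series(index=list(mds), dtype=float)
    for ind in mds:
        m = meta[ind]
        pi_vals = means[ind]
        if m.direction == "less_is_better":
            ref = float(pi_vals.min())
            scores[ind] = pi_vals / ref if mode == "literal_ratio" else ref / pi_vals
        elif m.direction == "optimum":
            ref = float(m.optimum_target)  # type: ignore[arg-type]
            if mode == "literal_ratio":
                scores[ind] = pi_vals / ref
            else:
                scores[ind] = np.minimum(pi_vals / ref, ref / pi_vals)
        else:  # more_is_better
            ref = float(pi_vals.max())
            scores[ind] = pi_vals / ref
        if ref <= 0:
            raise NormalizationError(f"non-positive reference for indicator {ind!r}")
        refs[ind] = ref
    return NormalizedScores(scores=scores, references=refs, mode=mode)


def shi_area(
    scores: NormalizedScores,
    config: SHIConfig | None = None,
    control: str | None = None,
    indicator_order: Sequence[str] | None = None,
) -> SHIResult:
    """Soil health index per treatment, plus percent change vs control."""
    config = config or SHIConfig()
    order = list(indicator_order) if indicator_order is not None else scores.indicators
    if sorted(order) != sorted(scores.indicators):
        raise ConfigurationError(
            "indicator_order must be a permutation of the scored indicators"
        )
    n = len(order)
    if n < 1:
        raise GeometryError("need at least one indicator")
    if config.formula_variant == "polygon_product" and n < 3:
        raise GeometryError(
            f"polygon_product needs >= 3 indicators for a polygon, got {n}"
        )
    control = control or scores.treatments[0]
    if control not in scores.treatments:
        raise ConfigurationError(f"control treatment {control!r} not in scores")

    sin_term = math.sin(2.0 * config.pi_constant / n)
    values = {}
    vertices = {}
    for trt in scores.treatments:
        st = scores.scores.loc[trt, order].to_numpy(dtype=float)
        if config.formula_variant == "squared_sum":
            values[trt] = 0.5 * float(np.sum(st**2)) * sin_term
        else:
            values[trt] = 0.5 * sin_term * float(np.sum(st * np.roll(st, -1)))
        angles = 2.0 * math.pi * np.arange(n) / n  # plotting geometry: exact pi
        vertices[trt] = [
            (float(r * math.cos(a)), float(r * math.sin(a)))
            for r, a in zip(st, angles)
        ]
    shi = pd.Series(values, name="SHI")
    pct = pd.Series(
        {t: percent_change(v, shi[control]) for t, v in shi.items()},
        name="percent_change",
    )
    return SHIResult(
        shi=shi,
        percent_change=pct,
        control=control,
        vertices=vertices,
        config=config,
        indicator_order=list(order),
    )


def percent_change(value: float, reference: float) -> float:
    """100 × (value − reference) / reference."""
    if reference <= 0:
        raise DomainError(f"reference must be > 0, got {reference}")
    return 100.0 * (value - reference) / reference
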
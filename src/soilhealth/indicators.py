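"""Indicator tables: the samples × indicators matrix every stage consumes.

An :class:`IndicatorTable` wraps a pandas DataFrame with three identifier
columns (``sample_id``, ``treatment``, ``replicate``) followed by one numeric
column per soil/plant indicator (SOC in g·kg⁻¹, AP/AK/Se/Zn in mg·kg⁻¹,
SMC in %, pH, EC, ORP, diversity metrics, ...). Validation is strict:
duplicate sample ids, missing cells and non-numeric cells are rejected with
row/column-level messages rather than silently imputed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ValidationError

ID_COLUMNS = ("sample_id", "treatment", "replicate")

VALID_DIRECTIONS = ("more_is_better", "less_is_better", "optimum")


@dataclass(frozen=True)
class IndicatorMeta:
    """Scoring metadata for one indicator.

    direction
        ``more_is_better`` (e.g. SOC, AK), ``less_is_better`` (e.g. EC for
        saline soils) or ``optimum`` (e.g. pH, best at a target value).
    optimum_target
        Required when ``direction == "optimum"``, forbidden otherwise.
    """

    direction: str = "more_is_better"
    optimum_target: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in VALID_DIRECTIONS:
            raise ValidationError(
                f"direction must be one of {VALID_DIRECTIONS}, got {self.direction!r}"
            )
        if self.direction == "optimum":
            if self.optimum_target is None or self.optimum_target <= 0:
                raise ValidationError(
                    "direction='optimum' requires optimum_target > 0, "
                    f"got {self.optimum_target!r}"
                )
        elif self.optimum_target is not None:
            raise ValidationError(
                f"optimum_target given for direction={self.direction!r}; "
                "only valid with direction='optimum'"
            )


@dataclass
class IndicatorTable:
    """Validated samples × indicators table with treatment/replicate labels."""

    data: pd.DataFrame
    meta: Mapping[str, IndicatorMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = validate_indicator_frame(self.data)

    @property
    def indicator_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ID_COLUMNS]

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.data["treatment"]))

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def values(self) -> pd.DataFrame:
        """Numeric matrix indexed by sample_id (samples × indicators)."""
        return self.data.set_index("sample_id")[self.indicator_names]

    def treatment_means(self) -> pd.DataFrame:
        """Per-treatment mean of every indicator (treatments × indicators)."""
        return (
            self.data.groupby("treatment", sort=False)[self.indicator_names].mean()
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(
        cls, path: str | Path, meta: Mapping[str, IndicatorMeta] | None = None
    ) -> "IndicatorTable":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"indicator table not found: {path}")
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        frame = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "treatment": str})
        return cls(frame, meta or {})


def validate_indicator_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Schema-check an indicator frame; raise ValidationError with row/column detail."""
    missing_cols = [c for c in ID_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ValidationError(f"missing required column(s): {', '.join(missing_cols)}")

    dupes = frame["sample_id"][frame["sample_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicated sample_id(s): {sorted(set(map(str, dupes)))}")

    indicator_cols = [c for c in frame.columns if c not in ID_COLUMNS]
    if not indicator_cols:
        raise ValidationError("table has no indicator columns")
    if len(set(indicator_cols)) != len(indicator_cols):
        raise ValidationError("indicator column names are not unique")

    frame = frame.copy()
    problems: list[str] = []
    for col in indicator_cols:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.loc[numeric.isna(), "sample_id"]
        for sid, raw in zip(bad, frame.loc[numeric.isna(), col]):
            if pd.isna(raw):
                problems.append(f"missing value in indicator {col!r}, sample {sid!r}")
            else:
                problems.append(
                    f"non-numeric cell {raw!r} in indicator {col!r}, sample {sid!r}"
                )
        frame[col] = numeric
    if problems:
        raise ValidationError("; ".join(problems))
    return frame


def read_meta_yaml(path: str | Path) -> dict[str, IndicatorMeta]:
    """Load per-indicator metadata from a YAML/JSON mapping.

    Expected shape::

        SOC: {direction: more_is_better}
        pH:  {direction: optimum, optimum_target: 6.5}
    """
    import yaml

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"metadata file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a mapping of indicator -> metadata")
    out: dict[str, IndicatorMeta] = {}
    for name, spec in raw.items():
        if isinstance(spec, str):
            spec = {"direction": spec}
        if not isinstance(spec, dict):
            raise ValidationError(f"{path}: entry {name!r} must be a mapping or string")
        try:
            out[str(name)] = IndicatorMeta(**spec)
        except (TypeError, ValidationError) as exc:
            raise ValidationError(f"{path}: entry {name!r}: {exc}") from exc
    return out
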
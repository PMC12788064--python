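"""Alpha-diversity estimators used as soil-biology indicators.

Observed richness, Chao1 (bias-corrected by default), ACE and Shannon
entropy (natural log by default), computed from nonnegative integer count
vectors. No rarefaction is performed here: if samples differ in sequencing
depth, normalize before calling (documented caller responsibility).
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptySampleError, UndefinedEstimatorError, ValidationError


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValidationError(f"counts must be a 1-D vector, got shape {arr.shape}")
    if arr.size == 0:
        raise EmptySampleError("empty counts vector")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError("counts must be numeric")
    if np.any(arr < 0):
        raise ValidationError("counts must be nonnegative")
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError("counts must be integers")
    arr = arr.astype(np.int64)
    if arr.sum() == 0:
        raise EmptySampleError("all counts are zero; diversity is undefined")
    return arr


def observed_richness(counts) -> int:
    """Number of taxa with at least one individual."""
    return int(np.count_nonzero(_as_counts(counts)))


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimator.

    Bias-corrected form (default): S_obs + F1(F1-1)/(2(F2+1)), defined for
    all inputs. Classic form: S_obs + F1^2/(2 F2), undefined when there are
    singletons but no doubletons.
    """
    arr = _as_counts(counts)
    s_obs = int(np.count_nonzero(arr))
    f1 = int(np.count_nonzero(arr == 1))
    f2 = int(np.count_nonzero(arr == 2))
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        if f1 == 0:
            return float(s_obs)
        raise UndefinedEstimatorError(
            "classic Chao1 is undefined with singletons but no doubletons "
            "(F2 = 0); use bias_corrected=True"
        )
    return s_obs + f1 * f1 / (2.0 * f2)


def ace(counts, rare_threshold: int = 10) -> float:
    """Abundance-based Coverage Estimator.

    Taxa with 1..rare_threshold individuals form the rare group; sample
    coverage C = 1 - F1/N_rare; ACE = S_abund + S_rare/C + (F1/C) * gamma^2
    with the squared coefficient of variation gamma^2 floored at 0.
    """
    arr = _as_counts(counts)
    if rare_threshold < 1:
        raise ValidationError(f"rare_threshold must be >= 1, got {rare_threshold}")
    arr = arr[arr > 0]
    rare = arr[arr <= rare_threshold]
    s_abund = int(np.count_nonzero(arr > rare_threshold))
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int(np.count_nonzero(rare == 1))
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        raise UndefinedEstimatorError(
            "ACE is undefined when every rare taxon is a singleton "
            "(sample coverage = 0)"
        )
    freqs = np.bincount(rare, minlength=rare_threshold + 1)
    i = np.arange(rare_threshold + 1)
    sum_term = float(np.sum(i * (i - 1) * freqs))
    if n_rare > 1:
        gamma_sq = max(
            0.0, (s_rare / coverage) * sum_term / (n_rare * (n_rare - 1)) - 1.0
        )
    else:
        gamma_sq = 0.0
    return s_abund + s_rare / coverage + (f1 / coverage) * gamma_sq


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i (natural log unless base given)."""
    arr = _as_counts(counts)
    arr = arr[arr > 0]
    p = arr / arr.sum()
    h = float(-np.sum(p * np.log(p)))
    if base is not None:
        if base <= 0 or base == 1:
            raise ValidationError(f"log base must be positive and != 1, got {base}")
        h /= math.log(base)
    return max(h, 0.0)


def alpha_diversity_table(
    abundance: pd.DataFrame, rare_threshold: int = 10, base: float | None = None
) -> pd.DataFrame:
    """Per-sample metric table from a taxa × samples count frame.

    Columns: sample_id, richness, chao1, ace, shannon.
    """
    records = []
    for sample in abundance.columns:
        counts = abundance[sample].to_numpy()
        records.append(
            {
                "sample_id": sample,
                "richness": observed_richness(counts),
                "chao1": chao1(counts),
                "ace": ace(counts, rare_threshold=rare_threshold),
                "shannon": shannon(counts, base=base),
            }
        )
    return pd.DataFrame.from_records(records)


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Load a taxa × samples CSV/TSV (first column = taxon identifier)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"abundance table not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.empty:
        raise ValidationError(f"{path}: abundance table is empty")
    for col in frame.columns:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.isna().any():
            bad = frame.index[numeric.isna()][0]
            raise ValidationError(
                f"{path}: non-numeric count for taxon {bad!r}, sample {col!r}"
            )
        frame[col] = numeric
    return frame
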
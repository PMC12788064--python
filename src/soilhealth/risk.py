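"""Selenium dietary-exposure risk, enrichment compliance, and economics.

EDI = (C × IR × conversion) / BW, HRI = EDI / RfD; a produce sample is
"Se-enriched" when its dry-weight Se concentration falls in the
GH/T 1135-2024 band [0.15, 1.0] mg·kg⁻¹ (both bounds inclusive).
Economic benefit EB = yield × price − cost, in currency per hectare.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .errors import DomainError

#: standard selenium oral reference dose, mg·kg⁻¹·day⁻¹
SE_RFD = 5e-3

#: GH/T 1135-2024 Se-enriched produce band, mg·kg⁻¹ dry weight
SE_ENRICHED_MIN = 0.15
SE_UPPER_LIMIT = 1.0

BELOW_ENRICHED = "below_enriched"
ENRICHED_WITHIN_LIMIT = "enriched_within_limit"
EXCEEDS_UPPER_LIMIT = "exceeds_upper_limit"


@dataclass(frozen=True)
class ExposureParams:
    """Inputs of the intake model.

    concentration: element concentration in edible tissue, mg·kg⁻¹.
    intake_rate: daily vegetable consumption, kg·day⁻¹.
    body_weight: consumer body weight, kg.
    rfd: oral reference dose, mg·kg⁻¹·day⁻¹.
    conversion: dry-to-fresh factor applied to the concentration when it is
        reported on a dry-weight basis (dimensionless, default 1).
    """

    concentration: float
    intake_rate: float
    body_weight: float
    rfd: float = SE_RFD
    conversion: float = 1.0

    def __post_init__(self) -> None:
        for name in ("concentration", "intake_rate", "body_weight", "rfd", "conversion"):
            value = getattr(self, name)
            if value <= 0:
                raise DomainError(f"{name} must be > 0, got {value}")


@dataclass
class RiskEconReport:
    edi: float
    hri: float
    enrichment_class: str
    economic_benefit: float | None
    params: dict

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    def table(self) -> str:
        rows = [
            ("EDI (mg·kg⁻¹·day⁻¹)", f"{self.edi:.4g}"),
            ("HRI (—)", f"{self.hri:.4g}"),
            ("Se enrichment class", self.enrichment_class),
        ]
        if self.economic_benefit is not None:
            rows.append(("EB (currency·ha⁻¹)", f"{self.economic_benefit:.2f}"))
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def estimated_daily_intake(params: ExposureParams) -> float:
    """EDI in mg per kg body weight per day."""
    return params.concentration * params.intake_rate * params.conversion / params.body_weight


def hazard_risk_index(edi: float, rfd: float = SE_RFD) -> float:
    """HRI = EDI / RfD; values well below 1 indicate negligible risk."""
    if rfd <= 0:
        raise DomainError(f"rfd must be > 0, got {rfd}")
    if edi <= 0:
        raise DomainError(f"edi must be > 0, got {edi}")
    return edi / rfd


def se_enrichment_class(se_dw: float) -> str:
    """Classify a dry-weight Se concentration against the enrichment band."""
    if se_dw < 0:
        raise DomainError(f"concentration must be >= 0, got {se_dw}")
    if se_dw < SE_ENRICHED_MIN:
        return BELOW_ENRICHED
    if se_dw <= SE_UPPER_LIMIT:
        return ENRICHED_WITHIN_LIMIT
    return EXCEEDS_UPPER_LIMIT


def economic_benefit(yield_kg_ha: float, price: float, cost: float) -> float:
    """EB = yield × price − cost (may be negative when costs dominate)."""
    if yield_kg_ha < 0:
        raise DomainError(f"yield must be >= 0, got {yield_kg_ha}")
    if price < 0:
        raise DomainError(f"price must be >= 0, got {price}")
    if cost < 0:
        raise DomainError(f"cost must be >= 0, got {cost}")
    return yield_kg_ha * price - cost


def assess(
    params: ExposureParams,
    se_dw: float | None = None,
    yield_kg_ha: float | None = None,
    price: float | None = None,
    cost: float | None = None,
) -> RiskEconReport:
    """Full risk + economics report with inputs echoed."""
    edi = estimated_daily_intake(params)
    hri = hazard_risk_index(edi, params.rfd)
    cls = se_enrichment_class(se_dw if se_dw is not None else params.concentration)
    eb = None
    if yield_kg_ha is not None and price is not None and cost is not None:
        eb = economic_benefit(yield_kg_ha, price, cost)
    echoed = asdict(params)
    echoed.update({"se_dw": se_dw, "yield_kg_ha": yield_kg_ha, "price": price, "cost": cost})
    return RiskEconReport(
        edi=edi, hri=hri, enrichment_class=cls, economic_benefit=eb, params=echoed
    )
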
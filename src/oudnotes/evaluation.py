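"""Severity-distribution summaries and positive predictive values (PPV).

PPV here validates the severity score as a phenotype: the fraction of
patients inferred *moderate or severe* (criterion count >= 4, or a forced
severe classification) among a denominator of either (a) patients whose
notes yielded annotations, or (b) all sampled patients — the conservative
reading that charges the score for charts with no relevant documentation.

Strata are study groups or index-encounter reasons.  Control patients are
excluded from the index-reason stratification: they are order-indexed by
design and would otherwise swamp the opioid-order stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional

import pandas as pd

from .corpus import Group

__all__ = [
    "SeverityDistribution",
    "PPVResult",
    "severity_distribution",
    "ppv",
    "pooled_ppv",
    "round_half_up",
]

CATEGORIES = ("none", "mild", "moderate", "severe")
STRATIFIERS = ("group", "index_reason")

#: Score strictly above this endorses the phenotype under ``strict_gt4``.
GT4_THRESHOLD = 4


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), matching printed precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SeverityDistribution:
    """Category counts for one stratum of scored patients."""

    stratum: str
    counts: dict[str, int]           # category -> patient count
    n_annotated: int
    n_sampled: Optional[int] = None
    n_gt4: int = 0                   # patients with score > 4 (strict mode numerator)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_annotated:
            raise ValueError("category counts must sum to n_annotated")
        if self.n_sampled is not None and self.n_annotated > self.n_sampled:
            raise ValueError("n_annotated exceeds n_sampled")


def severity_distribution(
    scores: pd.DataFrame,
    stratifier: str = "group",
    n_sampled: Mapping[str, int] | None = None,
) -> list[SeverityDistribution]:
    """Per-stratum severity-category counts from a ``score_corpus`` table.

    ``stratifier`` is ``"group"`` or ``"index_reason"`` (the latter excludes
    the control group).  ``n_sampled`` optionally supplies the designed
    sample size per stratum, enabling all-sampled denominators.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"stratifier must be one of {STRATIFIERS}, got {stratifier!r}")
    if scores.empty:
        return []
    frame = scores
    if stratifier == "index_reason":
        frame = frame[frame["group"] != Group.CONTROL.value]
    out = []
    for stratum, sub in frame.groupby(stratifier, sort=True):
        counts = {c: int((sub["category"] == c).sum()) for c in CATEGORIES}
        out.append(
            SeverityDistribution(
                stratum=str(stratum),
                counts=counts,
                n_annotated=int(len(sub)),
                n_sampled=None if n_sampled is None else int(n_sampled[str(stratum)]),
                n_gt4=int((sub["score"] > GT4_THRESHOLD).sum()),
            )
        )
    return out


@dataclass(frozen=True)
class PPVResult:
    """A positive predictive value with its exact fraction.

    ``value`` is the PPV rounded half-up to 2 decimals, or ``None`` when the
    denominator is zero (undefined is reported, never silently 0).
    """

    stratum: str
    denominator_mode: str
    numerator: int
    denominator: int
    value: Optional[float]

    @property
    def defined(self) -> bool:
        return self.value is not None


def _numerator(dist: SeverityDistribution, strict_gt4: bool) -> int:
    if strict_gt4:
        return dist.n_gt4
    return dist.counts["moderate"] + dist.counts["severe"]


def _denominator(dist: SeverityDistribution, mode: str) -> int:
    if mode == "annotated":
        return dist.n_annotated
    if mode == "all_sampled":
        if dist.n_sampled is None:
            raise ValueError(
                f"stratum {dist.stratum!r}: all_sampled mode requires n_sampled"
            )
        return dist.n_sampled
    raise ValueError(f"denominator_mode must be 'annotated' or 'all_sampled', got {mode!r}")


def ppv(
    dist: SeverityDistribution,
    denominator_mode: str = "annotated",
    strict_gt4: bool = False,
) -> PPVResult:
    """PPV for detecting moderate-or-severe OUD in one stratum.

    ``strict_gt4=True`` switches the numerator to score strictly greater
    than 4 (a fidelity experiment; the default >=4 numerator is the reading
    consistent with "moderate or severe").
    """
    num = _numerator(dist, strict_gt4)
    den = _denominator(dist, denominator_mode)
    value = None if den == 0 else round_half_up(num / den, 2)
    return PPVResult(
        stratum=dist.stratum,
        denominator_mode=denominator_mode,
        numerator=num,
        denominator=den,
        value=value,
    )


def pooled_ppv(
    distributions: list[SeverityDistribution],
    denominator_mode: str = "annotated",
    strict_gt4: bool = False,
    stratum: str = "pooled",
) -> PPVResult:
    """PPV pooled over strata: numerators and denominators sum before dividing."""
    if not distributions:
        raise ValueError("need at least one stratum to pool")
    num = sum(_numerator(d, strict_gt4) for d in distributions)
    den = sum(_denominator(d, denominator_mode) for d in distributions)
    value = None if den == 0 else round_half_up(num / den, 2)
    return PPVResult(
        stratum=stratum,
        denominator_mode=denominator_mode,
        numerator=num,
        denominator=den,
        value=value,
    )


def distribution_frame(distributions: list[SeverityDistribution]) -> pd.DataFrame:
    """Tabulate distributions (one row per stratum) for CSV export."""
    return pd.DataFrame(
        [
            {
                "stratum": d.stratum,
                **d.counts,
                "n_annotated": d.n_annotated,
                "n_sampled": d.n_sampled,
            }
            for d in distributions
        ]
    )


def ppv_frame(results: list[PPVResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "denominator_mode": r.denominator_mode,
                "numerator": r.numerator,
                "denominator": r.denominator,
                "ppv": r.value,
            }
            for r in results
        ]
    )
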
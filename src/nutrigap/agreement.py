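"""Linearly weighted kappa for paired ordinal burden ratings.

When the same nutrient gap is rated both from biomarker evidence and from
nonbiomarker evidence (dietary adequacy, food-group intake, food supply),
the agreement between the two rating routes can be quantified with the
weighted kappa statistic. Ratings live on the fixed 4-level burden scale
(0-3), so the statistic uses linear agreement weights

    w_ij = 1 - |i - j| / (k - 1),    k = 4,

which credit near-misses in proportion to how close the two ratings are:

    kappa_w = (p_o - p_e) / (1 - p_e)

with p_o the weighted observed agreement and p_e the weighted agreement
expected from the marginal rating distributions alone. kappa_w = 1 means
perfect agreement; 0 means chance-level agreement. When the margins are
degenerate (both raters always give the same single category) p_e = 1 and
the statistic is undefined; this is signalled, not silently NaN'd.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .burden import BurdenCode
from .evidence import EvidenceType


@dataclass(frozen=True)
class RatingPair:
    """One paired rating (rater A vs rater B) with optional tags."""

    a: int
    b: int
    nutrient: Optional[str] = None
    stratum: Optional[str] = None


@dataclass(frozen=True)
class ContingencyTable:
    """k x k cross-tabulation of paired ordinal ratings."""

    counts: np.ndarray  # shape (k, k), cell (i, j): A == i and B == j

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("contingency table must be square")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        if c.sum() < 1:
            raise ValueError("contingency table must contain at least one pair")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class KappaResult:
    kappa: Optional[float]
    observed_agreement: float
    expected_agreement: float
    n_pairs: int

    @property
    def undefined(self) -> bool:
        return self.kappa is None


def contingency(pairs: Sequence[RatingPair], k: int = 4) -> ContingencyTable:
    """Cross-tabulate rating pairs on a fixed k-category scale.

    The scale stays k x k even when some categories are unobserved, so
    kappas are comparable across strata.
    """
    if not pairs:
        raise ValueError("need at least one rating pair")
    counts = np.zeros((k, k), dtype=int)
    for p in pairs:
        if not (0 <= p.a < k and 0 <= p.b < k):
            raise ValueError(f"rating pair ({p.a}, {p.b}) outside 0..{k - 1}")
        counts[p.a, p.b] += 1
    return ContingencyTable(counts=counts)


def linear_weights(k: int) -> np.ndarray:
    """Linear agreement weight matrix w_ij = 1 - |i - j|/(k - 1)."""
    idx = np.arange(k)
    return 1.0 - np.abs(idx[:, None] - idx[None, :]) / (k - 1)


def linear_weighted_kappa(t: ContingencyTable) -> KappaResult:
    """Weighted kappa with linear weights from a contingency table.

    Returns ``kappa=None`` (undefined) when the expected weighted agreement
    equals 1, i.e. the margins carry no variation at all.
    """
    c = np.asarray(t.counts, dtype=float)
    n = c.sum()
    p = c / n
    w = linear_weights(t.k)
    p_o = float((w * p).sum())
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_e = float((w * np.outer(row, col)).sum())
    if np.isclose(p_e, 1.0, atol=1e-14):
        return KappaResult(
            kappa=None, observed_agreement=p_o, expected_agreement=p_e, n_pairs=int(n)
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=float(kappa),
        observed_agreement=p_o,
        expected_agreement=p_e,
        n_pairs=int(n),
    )


def stratified_kappa(
    pairs: Sequence[RatingPair], by: str = "stratum", k: int = 4
) -> dict[str, KappaResult]:
    """Per-stratum weighted kappas plus the pooled ``overall`` kappa.

    ``by`` selects the tag to stratify on (``"stratum"`` or ``"nutrient"``).
    Strata whose margins are degenerate come back with an undefined kappa.
    """
    if by not in ("stratum", "nutrient"):
        raise ValueError("stratify by 'stratum' or 'nutrient'")
    groups: dict[str, list[RatingPair]] = defaultdict(list)
    for p in pairs:
        groups[getattr(p, by) or "(untagged)"].append(p)
    out = {
        name: linear_weighted_kappa(contingency(g, k=k))
        for name, g in sorted(groups.items())
    }
    out["overall"] = linear_weighted_kappa(contingency(pairs, k=k))
    return out


_NONBIOMARKER = (
    EvidenceType.INDIVIDUAL_DIET,
    EvidenceType.HOUSEHOLD_DIET,
    EvidenceType.FOOD_SUPPLY,
    EvidenceType.FOOD_GROUP,
)


def pair_biomarker_nonbiomarker(
    records: Sequence[tuple[str, str, EvidenceType, BurdenCode, float]],
    stratify_by_evidence_type: bool = True,
) -> list[RatingPair]:
    """Pair each qualifying nonbiomarker point with its biomarker reference.

    ``records`` are (nutrient, group, evidence_type, burden code, weight
    score) for the points that qualified for the quantitative burden score;
    ``group`` is typically a country or area label. Within each
    (nutrient, group) cell the biomarker point with the highest weight
    score is the reference (rater A); every nonbiomarker point contributes
    one pair (rater B), tagged with its evidence type as the stratum.
    Cells without a biomarker point yield no pairs.
    """
    reference: dict[tuple[str, str], tuple[BurdenCode, float]] = {}
    for nutrient, group, etype, code, weight in records:
        if etype is EvidenceType.BIOMARKER:
            key = (nutrient, group)
            if key not in reference or weight > reference[key][1]:
                reference[key] = (code, weight)
    pairs: list[RatingPair] = []
    for nutrient, group, etype, code, weight in records:
        if etype not in _NONBIOMARKER:
            continue
        ref = reference.get((nutrient, group))
        if ref is None:
            continue
        pairs.append(
            RatingPair(
                a=int(ref[0]),
                b=int(code),
                nutrient=nutrient,
                stratum=etype.value if stratify_by_evidence_type else None,
            )
        )
    return pairs
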
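"""Transposon-activity statistics of a sample relative to a reference sample.

Solo LTRs are left behind by recombination between a retrotransposon's two
LTRs, so the ratio of LTR reads to full-element (internal-region) reads
tracks transposition/excision turnover.  Two statistics summarise how a
sample's LTR pool is perturbed relative to a designated reference:

* Ta1 — the mean over families of (LTR_n/TY_n)/(LTR_ref,n/TY_ref,n):
  copy-number sensitive, blind to LTR sequence diversity.
* Ta2 — (SI/TY)/(SI_ref/TY_ref), where SI is the Shannon index of the
  sample's pooled LTR variant abundances and TY the total full-element
  count: sensitive to diversity change per element.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .amplicon import FeatureCounts

__all__ = ["ActivityUndefinedError", "ActivityResult", "ta1", "ta2", "activity_result"]


class ActivityUndefinedError(ValueError):
    """A required count is zero/absent, so the statistic is not defined."""


@dataclass
class ActivityResult:
    ta1: Optional[float]
    ta2: Optional[float]
    reference_id: str
    per_family_ratios: dict[str, float]


def _family_ratio(fc: FeatureCounts, family: str, role: str) -> float:
    ty = fc.ty_counts.get(family, 0)
    if ty <= 0:
        raise ActivityUndefinedError(
            f"{role} sample {fc.sample_id!r}: no full-element (TY) counts for {family}"
        )
    return fc.ltr_total(family) / ty


def ta1(sample: FeatureCounts, reference: FeatureCounts) -> ActivityResult:
    """Mean per-family (LTR/TY) ratio change versus the reference sample.

    The family set is taken from the reference; a missing family or a zero
    TY/reference-LTR count raises ActivityUndefinedError naming the family —
    a mean over a changed family set would not be comparable.
    """
    families = sorted(reference.ty_counts)
    if not families:
        raise ActivityUndefinedError("reference sample has no families")
    ratios: dict[str, float] = {}
    for fam in families:
        num = _family_ratio(sample, fam, "query")
        den = _family_ratio(reference, fam, "reference")
        if den == 0:
            raise ActivityUndefinedError(
                f"reference sample {reference.sample_id!r}: no LTR counts for {fam}"
            )
        ratios[fam] = num / den
    return ActivityResult(
        ta1=float(np.mean(list(ratios.values()))),
        ta2=None,
        reference_id=reference.sample_id,
        per_family_ratios=ratios,
    )


def ta2(sample_si: float, sample_ty_total: float, ref_si: float, ref_ty_total: float) -> float:
    """Shannon-per-element ratio change: (SI/TY) / (SI_ref/TY_ref)."""
    if sample_ty_total <= 0 or ref_ty_total <= 0:
        raise ActivityUndefinedError("TY totals must be positive")
    if ref_si <= 0:
        raise ActivityUndefinedError("reference Shannon index must be positive")
    return (sample_si / sample_ty_total) / (ref_si / ref_ty_total)


def activity_result(
    sample: FeatureCounts,
    reference: FeatureCounts,
    sample_si: float,
    ref_si: float,
) -> ActivityResult:
    """Both statistics in one report; SI values come from the diversity module."""
    res = ta1(sample, reference)
    res.ta2 = ta2(
        sample_si,
        sum(sample.ty_counts.values()),
        ref_si,
        sum(reference.ty_counts.values()),
    )
    return res
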
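"""End-to-end per-sample profiling: reads -> counts -> OTUs -> diversity."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from . import amplicon
from .amplicon import FeatureCounts, OTUAssignment
from .diversity import DiversityProfile, diversity_profile

__all__ = ["SampleProfile", "profile_sample"]


@dataclass
class SampleProfile:
    counts: FeatureCounts
    otus: Optional[OTUAssignment]  # None when the sample has no LTR variants
    diversity: Optional[DiversityProfile]
    n_pairs: int
    n_merged: int
    n_assigned: int


def profile_sample(
    pairs: Sequence[tuple[str, str, list[int], str, list[int]]],
    panel,
    *,
    sample_id: str = "sample",
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
    min_identity: float = 0.80,
    otu_cutoff: float = 0.03,
    linkage: str = "average",
    otu_level: bool = True,
) -> SampleProfile:
    """Run merge -> assign -> dereplicate -> cluster -> diversity on one sample.

    ``pairs`` are (pair_id, r1_seq, r1_qual, r2_seq, r2_qual) tuples.  Family
    assignment is cached per distinct merged sequence, so deeply sequenced
    low-diversity samples cost one alignment pass per variant.  Diversity is
    computed on OTU-aggregated abundances by default (``otu_level=False``
    switches to raw variant abundances).
    """
    merged = []
    for pair_id, r1, q1, r2, q2 in pairs:
        m = amplicon.merge_pairs(
            r1, q1, r2, q2,
            min_overlap=min_overlap,
            max_mismatch_density=max_mismatch_density,
            pair_id=pair_id,
        )
        if m is not None:
            merged.append(m)

    cache: dict[str, Optional[tuple[str, str]]] = {}
    assigned = []
    for m in merged:
        if m.sequence not in cache:
            cache[m.sequence] = amplicon.assign_family(
                m.sequence, panel, min_identity=min_identity
            )
        hit = cache[m.sequence]
        if hit is not None:
            assigned.append((m.sequence, hit[0], hit[1]))

    counts = amplicon.dereplicate(assigned, sample_id=sample_id)
    variants = counts.pooled_variant_sequences()
    abundances = counts.pooled_variant_counts()
    otus = div = None
    if variants:
        dist = amplicon.pairwise_identity(variants)
        otus = amplicon.cluster_otus(dist, cutoff=otu_cutoff, method=linkage)
        labels = [otus.labels[i] for i in range(len(variants))] if otu_level else None
        div = diversity_profile(abundances, otu_labels=labels)
    return SampleProfile(
        counts=counts,
        otus=otus,
        diversity=div,
        n_pairs=len(pairs),
        n_merged=len(merged),
        n_assigned=len(assigned),
    )
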
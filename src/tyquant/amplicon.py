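"""Paired amplicon reads -> per-family LTR-variant and full-element count tables.

The stages mirror a conventional amplicon workflow: merge mate pairs on their
overlap, assign each merged read to a Ty family and element type (internal
region vs LTR) by global alignment against a reference panel, collapse
identical LTR sequences into variants, build a pairwise distance matrix, and
cluster variants into OTUs at a distance cutoff.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Seq import reverse_complement

__all__ = [
    "MergedRead",
    "FeatureCounts",
    "OTUAssignment",
    "merge_pairs",
    "assign_family",
    "dereplicate",
    "pairwise_identity",
    "global_identity",
    "cluster_otus",
]

LTR = "LTR"
INTERNAL = "internal"

_LINKAGES = ("single", "complete", "average")


@dataclass
class MergedRead:
    """A successfully joined mate pair."""

    sequence: str
    quality: list[int]
    source_pair_id: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality lengths differ")


@dataclass
class FeatureCounts:
    """Per-sample counts of LTR variants and full elements, keyed by family.

    ``ltr_counts[family]`` maps each distinct LTR variant sequence to its read
    count; ``ty_counts[family]`` counts internal-region (full-element) reads.
    """

    sample_id: str
    ltr_counts: dict[str, Counter] = field(default_factory=dict)
    ty_counts: dict[str, int] = field(default_factory=dict)

    def ltr_total(self, family: str) -> int:
        return sum(self.ltr_counts.get(family, Counter()).values())

    def pooled_variant_counts(self) -> list[int]:
        """All-family LTR variant abundance vector (order: family, then seq)."""
        out: list[int] = []
        for fam in sorted(self.ltr_counts):
            for seq in sorted(self.ltr_counts[fam]):
                out.append(self.ltr_counts[fam][seq])
        return out

    def pooled_variant_sequences(self) -> list[str]:
        out: list[str] = []
        for fam in sorted(self.ltr_counts):
            out.extend(sorted(self.ltr_counts[fam]))
        return out


@dataclass
class OTUAssignment:
    """Cluster labels for LTR variants at a distance cutoff."""

    labels: dict[int, int]
    cutoff: float
    method: str

    @property
    def n_otus(self) -> int:
        return len(set(self.labels.values()))


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def merge_pairs(
    r1_seq: str,
    r1_qual: Sequence[int],
    r2_seq: str,
    r2_qual: Sequence[int],
    *,
    min_overlap: int = 10,
    max_mismatch_density: float = 0.25,
    pair_id: str = "",
) -> Optional[MergedRead]:
    """Join a mate pair on the best-scoring overlap, or return None.

    R2 is reverse-complemented before the overlap search.  Among overlaps of
    length >= ``min_overlap`` whose mismatch density is <= the threshold, the
    one maximizing (matches - mismatches) wins; equal scores go to the longer
    overlap.  At mismatching overlap positions the higher-quality base is
    kept, with ties resolved in favour of R1.
    """
    if not r1_seq or not r2_seq:
        raise ValueError("empty read")
    s2 = reverse_complement(r2_seq)
    q2 = list(r2_qual)[::-1]
    a1, a2 = _as_bytes(r1_seq), _as_bytes(s2)
    n1, n2 = len(a1), len(a2)

    best_score, best_o = None, None
    for o in range(min(n1, n2), min_overlap - 1, -1):
        mism = int(np.count_nonzero(a1[n1 - o :] != a2[:o]))
        if mism / o > max_mismatch_density:
            continue
        score = o - 2 * mism
        if best_score is None or score > best_score:
            best_score, best_o = score, o
    if best_o is None:
        return None

    o = best_o
    head_seq, head_q = r1_seq[: n1 - o], list(r1_qual)[: n1 - o]
    tail_seq, tail_q = s2[o:], q2[o:]
    mid_seq, mid_q = [], []
    for i in range(o):
        b1, b2 = r1_seq[n1 - o + i], s2[i]
        qa, qb = r1_qual[n1 - o + i], q2[i]
        if b1 == b2:
            mid_seq.append(b1)
            mid_q.append(max(qa, qb))
        elif qb > qa:
            mid_seq.append(b2)
            mid_q.append(qb)
        else:  # qa >= qb: ties take the R1 base
            mid_seq.append(b1)
            mid_q.append(qa)
    return MergedRead(
        sequence=head_seq + "".join(mid_seq) + tail_seq,
        quality=head_q + mid_q + tail_q,
        source_pair_id=pair_id,
    )


def _make_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


_DEFAULT_ALIGNER = _make_aligner()


def global_identity(a: str, b: str, aligner: Optional[Align.PairwiseAligner] = None) -> float:
    """Fraction of matching columns in a global alignment, terminal gaps excluded.

    Scoring defaults: match +1, mismatch -1, gap -2.  Terminal-gap columns are
    dropped so that length-ragged sequences are compared over their shared span.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 1.0
    aligner = aligner or _DEFAULT_ALIGNER
    aln = aligner.align(a.upper(), b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    start, end = 0, len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols == 0:
        return 0.0
    matches = sum(1 for i in range(start, end) if row_a[i] == row_b[i] and row_a[i] != "-")
    return matches / cols


def assign_family(
    seq: str,
    panel,
    *,
    min_identity: float = 0.80,
    max_n_fraction: float = 0.10,
) -> Optional[tuple[str, str]]:
    """Assign a merged read to (family, element_type) by best panel identity.

    Returns None when the best identity is below ``min_identity`` or the read
    carries more than ``max_n_fraction`` ambiguous bases.  Ties go to the
    first reference in panel order (families sorted; internal before LTR).
    """
    if not seq:
        raise ValueError("empty sequence")
    if seq.upper().count("N") / len(seq) > max_n_fraction:
        return None
    best: Optional[tuple[str, str]] = None
    best_ident = -1.0
    for family, element_type, ref in panel.references():
        ident = global_identity(seq, ref)
        if ident > best_ident:
            best_ident, best = ident, (family, element_type)
    if best_ident < min_identity:
        return None
    return best


def dereplicate(
    assigned_reads: Sequence[tuple[str, str, str]],
    sample_id: str = "sample",
) -> FeatureCounts:
    """Collapse (sequence, family, element_type) triples into FeatureCounts.

    Identical LTR sequences within a family become one variant with a summed
    count; internal-region reads increment the family's full-element count.
    """
    fc = FeatureCounts(sample_id=sample_id)
    for seq, family, element_type in assigned_reads:
        if element_type == LTR:
            fc.ltr_counts.setdefault(family, Counter())[seq] += 1
        elif element_type == INTERNAL:
            fc.ty_counts[family] = fc.ty_counts.get(family, 0) + 1
        else:
            raise ValueError(f"unknown element type: {element_type!r}")
    return fc


def pairwise_identity(variants: Sequence[str]) -> np.ndarray:
    """Symmetric matrix of alignment distances (1 - identity), diagonal zero."""
    if len(variants) == 0:
        raise ValueError("need at least one sequence")
    n = len(variants)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - global_identity(variants[i], variants[j])
            dist[i, j] = dist[j, i] = d
    return dist


def _linkage_value(block: np.ndarray, method: str) -> float:
    if method == "single":
        return float(block.min())
    if method == "complete":
        return float(block.max())
    return float(block.mean())


def cluster_otus(dist: np.ndarray, cutoff: float = 0.03, method: str = "average") -> OTUAssignment:
    """Agglomerative clustering of variants into OTUs at a distance cutoff.

    Merging proceeds while the smallest inter-cluster linkage distance is
    <= ``cutoff`` and stops once it exceeds it.  Ties on the merge distance
    are broken toward the pair containing the lowest variant index.  OTU ids
    are numbered 0..k-1 in order of each cluster's lowest member index.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must be in [0, 1]")
    if method not in _LINKAGES:
        raise ValueError(f"method must be one of {_LINKAGES}")
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None  # (d, rep_i, rep_j, i, j)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                block = dist[np.ix_(clusters[i], clusters[j])]
                d = _linkage_value(block, method)
                key = (d, clusters[i][0], clusters[j][0])
                if best is None or key < best[:3]:
                    best = (d, clusters[i][0], clusters[j][0], i, j)
        if best is None or best[0] > cutoff:
            break
        _, _, _, i, j = best
        clusters[i] = sorted(clusters[i] + clusters[j])
        del clusters[j]
        clusters.sort(key=lambda c: c[0])
    clusters.sort(key=lambda c: c[0])
    labels = {idx: otu for otu, members in enumerate(clusters) for idx in members}
    return OTUAssignment(labels=labels, cutoff=cutoff, method=method)
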
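"""Seeded generators for every input the pipeline consumes.

Emulates an LTR-amplicon experiment over the five yeast Ty retrotransposon
families: a reference panel (one internal-region and one LTR sequence per
family), paired-end amplicon reads drawn from LTR-variant and internal
templates with per-base errors, phenotype tables drawn from a known linear
model of heat-shock survival, and gene sets with planted overlaps plus a
directed interaction network whose transposon out-neighborhood is known.

Every generator is driven by an explicit seed or numpy Generator, so that
identical configuration yields byte-identical outputs, and each output
carries ground truth the downstream modules can be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from . import amplicon
from .amplicon import INTERNAL, LTR

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "ReferencePanel",
    "SampleTruth",
    "make_panel",
    "make_variants",
    "simulate_sample",
    "simulate_phenotypes",
    "simulate_genesets",
    "PUBLISHED_COEFS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Published survival model: Survival45 = -2.39*TULA + 69.98*Ta2 + 152.43
PUBLISHED_COEFS = (-2.39, 69.98, 152.43)


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally impossible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the amplicon simulator.

    LTR amplicons span the whole LTR reference, so a mate pair overlaps by
    ``2*read_length - ltr_length`` bases; internal amplicons use a window of
    ``2*read_length - overlap_length`` bases from the internal reference.
    """

    seed: int = 0
    n_families: int = 5
    ltr_length: int = 330
    internal_length: int = 1500
    n_variants_per_family: int = 4
    substitution_rate: float = 0.02
    abundance_concentration: float = 1.0
    read_length: int = 200
    overlap_length: int = 70
    sequencing_error_rate: float = 0.001
    n_reads_per_sample: int = 1000
    ltr_read_fraction: float = 0.5
    quality_score: int = 30

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        if self.ltr_length < 20:
            raise ConfigurationError("ltr_length must be >= 20")
        for name in ("substitution_rate", "sequencing_error_rate", "ltr_read_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if not (0 < self.overlap_length < self.read_length):
            raise ConfigurationError("need 0 < overlap_length < read_length")
        if self.ltr_length >= 2 * self.read_length:
            raise ConfigurationError("ltr_length must be < 2*read_length so pairs overlap")
        if self.internal_length < 2 * self.read_length - self.overlap_length:
            raise ConfigurationError("internal_length shorter than the internal amplicon window")
        if self.n_variants_per_family < 1:
            raise ConfigurationError("n_variants_per_family must be >= 1")
        if self.n_reads_per_sample < 1:
            raise ConfigurationError("n_reads_per_sample must be >= 1")

    @property
    def internal_window(self) -> int:
        return 2 * self.read_length - self.overlap_length

    def family_names(self) -> list[str]:
        return [f"Ty{i + 1}" for i in range(self.n_families)]


@dataclass
class ReferencePanel:
    """Internal-region and LTR reference sequences per Ty family."""

    internal: dict[str, str]
    ltr: dict[str, str]

    @property
    def families(self) -> list[str]:
        return sorted(self.internal)

    def references(self) -> Iterator[tuple[str, str, str]]:
        """Yield (family, element_type, sequence) in deterministic panel order."""
        for fam in self.families:
            yield fam, INTERNAL, self.internal[fam]
            yield fam, LTR, self.ltr[fam]


@dataclass
class SampleTruth:
    """Error-free ground truth for one simulated sample.

    ``variant_abundances`` holds, per family, the read-pair count of every
    LTR variant template; ``ty_counts`` the internal-region pair counts.
    ``true_shannon``/``true_chao1`` are closed-form values on the pooled
    variant abundance vector, recomputable by the diversity module.
    """

    sample_id: str
    variant_abundances: dict[str, dict[str, int]]
    ty_counts: dict[str, int]
    true_shannon: float
    true_chao1: float
    true_ta1: Optional[float] = None
    true_ta2: Optional[float] = None
    reference_id: Optional[str] = None

    def pooled_counts(self) -> list[int]:
        out: list[int] = []
        for fam in sorted(self.variant_abundances):
            for seq in sorted(self.variant_abundances[fam]):
                out.append(self.variant_abundances[fam][seq])
        return out

    def ltr_total(self, family: str) -> int:
        return sum(self.variant_abundances.get(family, {}).values())


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def make_panel(config: SimulationConfig, max_attempts: int = 100) -> ReferencePanel:
    """Generate a reference panel with unambiguous family assignment.

    LTR references are uniform-random sequences regenerated until every
    inter-family pairwise identity is below 0.70, so a read within 20% of its
    own family's LTR cannot be closer to another family's.
    """
    rng = np.random.default_rng(config.seed)
    fams = config.family_names()
    internal = {fam: _random_seq(rng, config.internal_length) for fam in fams}
    for _ in range(max_attempts):
        ltrs = [_random_seq(rng, config.ltr_length) for _ in fams]
        ok = all(
            amplicon.global_identity(ltrs[i], ltrs[j]) < 0.70
            for i in range(len(fams))
            for j in range(i + 1, len(fams))
        )
        if ok:
            return ReferencePanel(internal=internal, ltr=dict(zip(fams, ltrs)))
    raise ConfigurationError(
        "could not generate LTR references with inter-family identity < 0.70; "
        "ltr_length may be too short"
    )


def make_variants(
    panel: ReferencePanel, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, list[str]]:
    """Per-family LTR variant templates: substitution-mutated copies of the reference."""
    return {
        fam: [
            _mutate(rng, panel.ltr[fam], config.substitution_rate)
            for _ in range(config.n_variants_per_family)
        ]
        for fam in panel.families
    }


def _read_pair_from_template(
    template: str, config: SimulationConfig, rng: np.random.Generator
) -> tuple[str, str]:
    L = config.read_length
    r1 = template[:L]
    r2 = reverse_complement(template[-L:])
    if config.sequencing_error_rate > 0.0:
        r1 = _mutate(rng, r1, config.sequencing_error_rate)
        r2 = _mutate(rng, r2, config.sequencing_error_rate)
    return r1, r2


def simulate_sample(
    panel: ReferencePanel,
    config: SimulationConfig,
    abundances: Optional[dict[str, Sequence[float]]] = None,
    *,
    sample_id: str = "sample",
    variants: Optional[dict[str, list[str]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[tuple[str, str, list[int], str, list[int]]], SampleTruth]:
    """Draw one sample's paired reads and its ground truth.

    Returns ``(pairs, truth)`` where each pair is
    ``(pair_id, r1_seq, r1_qual, r2_seq, r2_qual)``.  ``abundances`` gives
    per-family variant weights (nonnegative, at least one positive); by
    default a symmetric Dirichlet draw with the configured concentration.
    """
    from . import diversity  # local import: truth is defined via the diversity module

    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if variants is None:
        variants = make_variants(panel, config, rng)
    fams = panel.families

    if abundances is None:
        conc = config.abundance_concentration
        abundances = {
            fam: rng.dirichlet(np.full(len(variants[fam]), conc)) for fam in fams
        }
    weights: dict[str, np.ndarray] = {}
    for fam in fams:
        w = np.asarray(abundances[fam], dtype=float)
        if w.size != len(variants[fam]):
            raise ValueError(f"{fam}: {len(variants[fam])} variants but {w.size} weights")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError(f"{fam}: weights must be nonnegative with at least one positive")
        weights[fam] = w / w.sum()

    qual = [config.quality_score] * config.read_length
    pairs: list[tuple[str, str, list[int], str, list[int]]] = []
    variant_abundances: dict[str, dict[str, int]] = {fam: {} for fam in fams}
    ty_counts: dict[str, int] = {fam: 0 for fam in fams}
    win = config.internal_window

    for i in range(config.n_reads_per_sample):
        fam = fams[rng.integers(len(fams))]
        if rng.random() < config.ltr_read_fraction:
            vi = rng.choice(len(weights[fam]), p=weights[fam])
            template = variants[fam][vi]
            variant_abundances[fam][template] = variant_abundances[fam].get(template, 0) + 1
        else:
            template = panel.internal[fam][:win]
            ty_counts[fam] += 1
        r1, r2 = _read_pair_from_template(template, config, rng)
        pairs.append((f"{sample_id}:{i}", r1, qual, r2, qual))

    pooled = [
        variant_abundances[fam][seq]
        for fam in sorted(variant_abundances)
        for seq in sorted(variant_abundances[fam])
    ]
    truth = SampleTruth(
        sample_id=sample_id,
        variant_abundances=variant_abundances,
        ty_counts=ty_counts,
        true_shannon=diversity.shannon(pooled) if pooled else float("nan"),
        true_chao1=diversity.chao1(pooled) if pooled else float("nan"),
    )
    return pairs, truth


def attach_truth_activity(truth: SampleTruth, reference: SampleTruth) -> SampleTruth:
    """Fill ``true_ta1``/``true_ta2`` of a truth record against a reference truth."""
    ratios = []
    for fam in sorted(reference.ty_counts):
        num = truth.ltr_total(fam) / truth.ty_counts[fam]
        den = reference.ltr_total(fam) / reference.ty_counts[fam]
        ratios.append(num / den)
    ty_s = sum(truth.ty_counts.values())
    ty_r = sum(reference.ty_counts.values())
    ta2 = (truth.true_shannon / ty_s) / (reference.true_shannon / ty_r)
    return replace(truth, true_ta1=float(np.mean(ratios)), true_ta2=ta2,
                   reference_id=reference.sample_id)


def simulate_phenotypes(
    n: int,
    coefs: tuple[float, float, float] = PUBLISHED_COEFS,
    noise_sd: float = 9.19,
    seed: int = 0,
    *,
    tula_range: tuple[float, float] = (60.0, 80.0),
    ta2_range: tuple[float, float] = (0.6, 1.2),
) -> pd.DataFrame:
    """Phenotype table drawn from the linear survival model plus Gaussian noise.

    ``coefs`` is (b_tula, b_ta2, intercept); defaults to the published fit
    Survival45 = -2.39*TULA + 69.98*Ta2 + 152.43 with noise_sd matching its
    standard error of estimate.  TULA (%) and Ta2 are uniform over ranges
    chosen so the noiseless predictor stays within [0, 100] survival.
    """
    if n < 4:
        raise ValueError("need n >= 4 observations for a two-predictor fit")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    b_tula, b_ta2, intercept = coefs
    tula = rng.uniform(*tula_range, size=n)
    ta2 = rng.uniform(*ta2_range, size=n)
    survival = b_tula * tula + b_ta2 * ta2 + intercept
    if noise_sd > 0:
        survival = survival + rng.normal(0.0, noise_sd, size=n)
    return pd.DataFrame(
        {
            "strain": [f"strain{i + 1}" for i in range(n)],
            "survival45": survival,
            "tula": tula,
            "ta2": ta2,
        }
    )


def simulate_genesets(
    sizes: tuple[int, int, int],
    planted_overlaps: tuple[int, int, int],
    universe_size: int,
    seed: int = 0,
    *,
    n_transposon_nodes: int = 5,
) -> tuple[set[str], set[str], set[str], nx.DiGraph, set[str]]:
    """Three gene sets with planted overlaps, plus a directed network.

    ``sizes`` = (|H|, |M|, |T|); ``planted_overlaps`` = (|H&M|, |H&T|, |H&M&T|).
    M&T outside H is left empty, so the pairwise and triple overlaps are exactly
    the planted counts.  The network's level-1 out-neighborhood of the
    transposon nodes equals T by construction; decoy edges between ordinary
    genes and into the transposon nodes are added and never change that.

    Returns (H, M, T, network, transposon_nodes).
    """
    size_h, size_m, size_t = sizes
    hm, ht, hmt = planted_overlaps
    cells = {
        "HMT": hmt,
        "HM": hm - hmt,
        "HT": ht - hmt,
        "H": size_h - hm - ht + hmt,
        "M": size_m - hm,
        "T": size_t - ht,
    }
    if min(cells.values()) < 0:
        raise ValueError(f"inconsistent overlap arithmetic: {cells}")
    n_distinct = sum(cells.values())
    if n_distinct > universe_size:
        raise ValueError("universe_size too small for the requested sets")

    rng = np.random.default_rng(seed)
    width = len(str(universe_size))
    universe = np.array([f"G{i:0{width}d}" for i in range(universe_size)])
    chosen = rng.choice(universe, size=n_distinct, replace=False)
    parts: dict[str, set[str]] = {}
    pos = 0
    for name in ("HMT", "HM", "HT", "H", "M", "T"):
        parts[name] = set(chosen[pos : pos + cells[name]])
        pos += cells[name]
    h = parts["H"] | parts["HM"] | parts["HT"] | parts["HMT"]
    m = parts["M"] | parts["HM"] | parts["HMT"]
    t = parts["T"] | parts["HT"] | parts["HMT"]

    transposon_nodes = {f"TY{i + 1}" for i in range(n_transposon_nodes)}
    net = nx.DiGraph()
    net.add_nodes_from(universe.tolist())
    for node in sorted(transposon_nodes):
        net.add_node(node, transposon=True)
    ty_list = sorted(transposon_nodes)
    for gene in sorted(t):  # every T gene gets at least one transposon parent
        net.add_edge(ty_list[int(rng.integers(len(ty_list)))], gene)
    # decoys: regulator -> transposons, and ordinary gene -> gene edges
    net.add_node("SPT23")
    for node in ty_list:
        net.add_edge("SPT23", node)
    non_t = sorted(set(universe.tolist()) - t - transposon_nodes)
    if len(non_t) >= 2:
        k = min(3 * size_t + 10, len(non_t) - 1)
        src = rng.choice(len(non_t), size=k)
        dst = rng.choice(len(non_t), size=k)
        for a, b in zip(src, dst):
            if a != b:
                net.add_edge(non_t[int(a)], non_t[int(b)])
    return h, m, t, net, transposon_nodes
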
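"""Generate the synthetic study inputs: reference panel, two amplicon
samples (a 30 C-like reference and a heat-stressed sample with a skewed,
less even LTR pool), an 8-strain phenotype table drawn from the survival
equation, and gene sets with planted overlaps.

Reads (large) go to scratch/sim/; small tables and truth values to results/.
"""

import json
from pathlib import Path

import numpy as np

from tyquant import io, synthgen

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"
SEED = 20260


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cfg = synthgen.SimulationConfig(
        seed=SEED, n_reads_per_sample=1000, sequencing_error_rate=0.0,
        substitution_rate=0.02, n_variants_per_family=4,
    )
    panel = synthgen.make_panel(cfg)
    io.write_panel_fasta(panel, SCRATCH / "panel.fasta")

    rng = np.random.default_rng(SEED)
    variants = synthgen.make_variants(panel, cfg, rng)
    # reference: even variant pool; stressed: one dominant variant per family
    even = {f: [1.0] * 4 for f in panel.families}
    skewed = {f: [8.0, 1.0, 0.5, 0.5] for f in panel.families}
    truths = {}
    for sid, ab in (("ref_30C", even), ("stress_37C", skewed)):
        pairs, truth = synthgen.simulate_sample(
            panel, cfg, abundances=ab, sample_id=sid, variants=variants, rng=rng
        )
        io.write_paired_fastq(pairs, SCRATCH / sid)
        truths[sid] = {
            "ty_counts": truth.ty_counts,
            "true_shannon": truth.true_shannon,
            "true_chao1": truth.true_chao1,
        }

    pheno = synthgen.simulate_phenotypes(8, noise_sd=9.19, seed=SEED)
    pheno.to_csv(RESULTS / "01_phenotypes.tsv", sep="\t", index=False)

    h, m, t, net, ty = synthgen.simulate_genesets(
        (10_000, 2_000, 1_500), (913, 698, 100), 50_000, seed=SEED
    )
    # gene sets are large; persist them only to scratch
    for name, genes in (("h_deg", h), ("m_core", m)):
        (SCRATCH / f"{name}.txt").write_text("\n".join(sorted(genes)) + "\n")
    (SCRATCH / "transposons.txt").write_text("\n".join(sorted(ty)) + "\n")
    with (SCRATCH / "network.tsv").open("w") as fh:
        fh.write("source\ttarget\n")
        for a, b in net.edges:
            fh.write(f"{a}\t{b}\n")

    (RESULTS / "01_truth.json").write_text(json.dumps(truths, indent=2) + "\n")
    print(f"wrote reads + gene sets to {SCRATCH}, truth + phenotypes to {RESULTS}")
    print(json.dumps(truths, indent=2))


if __name__ == "__main__":
    main()
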
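"""Build H-CORE and T-CORE from the simulated inputs and weigh the direct
(H&M) against the transposon-mediated (H&T) contribution."""

import json
from pathlib import Path

from tyquant import coresets, io

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SCRATCH / "network.tsv").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    h = set((SCRATCH / "h_deg.txt").read_text().split())
    m = set((SCRATCH / "m_core.txt").read_text().split())
    ty = set((SCRATCH / "transposons.txt").read_text().split())
    net = io.read_network_tsv(SCRATCH / "network.tsv")
    t = coresets.t_core(net, ty)
    w = coresets.overlap_weights(h, m, t)
    payload = {
        "h_core_size": len(h),
        "m_core_size": len(m),
        "t_core_size": len(t),
        "pct_direct": w.pct_direct,
        "pct_transposon": w.pct_transposon,
        "ratio": w.ratio,
    }
    (RESULTS / "04_overlap.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(
        f"|H|={len(h)}, |H&M|={len(h & m)} ({w.pct_direct:.2f}%), "
        f"|H&T|={len(h & t)} ({w.pct_transposon:.2f}%)"
    )
    print(f"direct : transposon-mediated weight ratio = {w.ratio:.2f}")


if __name__ == "__main__":
    main()
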
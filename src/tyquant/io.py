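"""Readers and writers for the plain-text formats the pipeline exchanges.

Paired FASTQ and panel FASTA go through Bio.SeqIO; tables are TSV via
pandas.  The counts table uses the long layout
(sample, family, element_type, variant_id, sequence, count) with TY rows
carrying an empty sequence.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import FeatureCounts, INTERNAL, LTR
from .synthgen import ReferencePanel

__all__ = [
    "write_paired_fastq",
    "read_paired_fastq",
    "write_panel_fasta",
    "read_panel_fasta",
    "write_counts_tsv",
    "read_counts_tsv",
    "read_gene_set_tsv",
    "read_network_tsv",
    "write_json",
]


def _fastq_records(pairs, mate: int):
    for pair_id, r1, q1, r2, q2 in pairs:
        seq, qual = (r1, q1) if mate == 1 else (r2, q2)
        rec = SeqRecord(Seq(seq), id=f"{pair_id}/{mate}", description="")
        rec.letter_annotations["phred_quality"] = list(qual)
        yield rec


def write_paired_fastq(pairs, prefix: str | Path) -> tuple[Path, Path]:
    """Write mate files ``<prefix>_R1.fastq`` and ``<prefix>_R2.fastq``."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq")
    p2 = prefix.with_name(prefix.name + "_R2.fastq")
    SeqIO.write(_fastq_records(pairs, 1), str(p1), "fastq")
    SeqIO.write(_fastq_records(pairs, 2), str(p2), "fastq")
    return p1, p2


def read_paired_fastq(r1_path: str | Path, r2_path: str | Path):
    """Load mate files back into (pair_id, r1, q1, r2, q2) tuples."""
    recs1 = list(SeqIO.parse(str(r1_path), "fastq"))
    recs2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError("mate files differ in record count")
    pairs = []
    for a, b in zip(recs1, recs2):
        pairs.append(
            (
                a.id.rsplit("/", 1)[0],
                str(a.seq),
                a.letter_annotations["phred_quality"],
                str(b.seq),
                b.letter_annotations["phred_quality"],
            )
        )
    return pairs


def write_panel_fasta(panel: ReferencePanel, path: str | Path) -> Path:
    records = [
        SeqRecord(Seq(seq), id=f"{fam}|{etype}", description="")
        for fam, etype, seq in panel.references()
    ]
    SeqIO.write(records, str(path), "fasta")
    return Path(path)


def read_panel_fasta(path: str | Path) -> ReferencePanel:
    internal: dict[str, str] = {}
    ltr: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fam, etype = rec.id.split("|", 1)
        (internal if etype == INTERNAL else ltr)[fam] = str(rec.seq)
    if set(internal) != set(ltr):
        raise ValueError("panel FASTA must pair one internal and one LTR record per family")
    return ReferencePanel(internal=internal, ltr=ltr)


def write_counts_tsv(counts_list: Iterable[FeatureCounts], path: str | Path) -> Path:
    rows = []
    for fc in counts_list:
        for fam in sorted(fc.ltr_counts):
            for i, seq in enumerate(sorted(fc.ltr_counts[fam])):
                rows.append(
                    (fc.sample_id, fam, LTR, f"{fam}.v{i}", seq, fc.ltr_counts[fam][seq])
                )
        for fam in sorted(fc.ty_counts):
            rows.append((fc.sample_id, fam, "TY", "", "", fc.ty_counts[fam]))
    df = pd.DataFrame(
        rows, columns=["sample", "family", "element_type", "variant_id", "sequence", "count"]
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_counts_tsv(path: str | Path) -> list[FeatureCounts]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for sample, sub in df.groupby("sample", sort=True):
        fc = FeatureCounts(sample_id=str(sample))
        for _, row in sub.iterrows():
            if row["element_type"] == LTR:
                from collections import Counter

                fc.ltr_counts.setdefault(row["family"], Counter())[row["sequence"]] += int(
                    row["count"]
                )
            else:
                fc.ty_counts[row["family"]] = fc.ty_counts.get(row["family"], 0) + int(
                    row["count"]
                )
        out.append(fc)
    return out


def read_gene_set_tsv(path: str | Path) -> tuple[set[str], dict[str, str]]:
    """Gene-list TSV with columns ``gene`` and optionally ``direction``."""
    df = pd.read_csv(path, sep="\t")
    genes = {str(g).strip() for g in df["gene"]}
    directions = (
        {str(g).strip(): str(d) for g, d in zip(df["gene"], df["direction"])}
        if "direction" in df.columns
        else {}
    )
    return genes, directions


def read_network_tsv(path: str | Path):
    """Edge-list TSV with columns ``source`` and ``target`` -> nx.DiGraph."""
    import networkx as nx

    df = pd.read_csv(path, sep="\t")
    net = nx.DiGraph()
    net.add_edges_from(
        (str(s).strip(), str(t).strip()) for s, t in zip(df["source"], df["target"])
    )
    return net


def write_json(obj, path: str | Path) -> Path:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return Path(path)
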
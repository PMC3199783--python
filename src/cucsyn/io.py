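"""Readers and writers for the pipeline's tab-separated and FASTA formats."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .linkage import CODE_OF, SYMBOL_OF, GeneticMap, GenotypeMatrix, PopulationType


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        [[SYMBOL_OF[int(c)] for c in row] for row in matrix.calls],
        index=matrix.individuals, columns=matrix.marker_ids,
    )
    df.index.name = "individual"
    df.to_csv(path, sep="\t")


def read_genotypes(path: str | Path, population_type: PopulationType) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    calls = np.array([[CODE_OF[c] for c in row] for row in df.to_numpy()],
                     dtype=np.int8)
    return GenotypeMatrix(population_type, list(df.index.astype(str)),
                          list(df.columns), calls)


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    rows = []
    for name, loci in gmap.groups.items():
        for mid, pos in loci:
            rows.append({
                "group": name,
                "chromosome_label": gmap.chromosome_labels.get(name, ""),
                "marker_id": mid,
                "position_cM": f"{pos:.1f}",
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", dtype={"group": str, "marker_id": str})
    groups: dict[str, list[tuple[str, float]]] = {}
    labels: dict[str, str] = {}
    for g, grp in df.groupby("group", sort=False):
        groups[g] = list(zip(grp["marker_id"], grp["position_cM"].astype(float)))
        lab = grp["chromosome_label"].iloc[0]
        if pd.notna(lab) and str(lab):
            labels[g] = str(lab)
    return GeneticMap(groups=groups, chromosome_labels=labels)


def write_primers(table: pd.DataFrame, path: str | Path) -> None:
    table[["marker_id", "primer_fwd", "primer_rev"]].to_csv(
        path, sep="\t", index=False)


def read_primers(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED repeat intervals: 0-based half-open, keyed by scaffold."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2])))
    return out


def write_hits(hits: list, path: str | Path) -> None:
    cols = ["marker_id", "assembly", "scaffold", "start", "end", "strand",
            "product_size", "product_sequence"]
    rows = [{c: getattr(h, c) for c in cols} for h in hits]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_anchored(anchored: list, path: str | Path) -> None:
    pd.DataFrame([asdict(a) for a in anchored]).to_csv(path, sep="\t", index=False)


def write_blocks(blocks: list, path: str | Path) -> None:
    rows = []
    for b in blocks:
        rows.append({
            "source_chromosome": b.source_chromosome,
            "target_chromosome": b.target_chromosome,
            "start_cM": round(b.start_cM, 1), "end_cM": round(b.end_cM, 1),
            "n_markers": b.n_markers,
            "n_discordant": len(b.discordant),
            "tau": "" if b.tau is None else round(b.tau, 3),
            "arrangement": b.arrangement,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, set):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")
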
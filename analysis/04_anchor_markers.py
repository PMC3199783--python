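#!/usr/bin/env python
"""Anchor consensus-map markers onto the derived-genome scaffolds.

Virtual PCR of each consensus marker's primer pair against the scaffold
FASTA, unique / multi-copy / no-hit classification, and chromosome
assignment: direct for markers on the derived genome's reference map,
transitive (majority chromosome, median cM of the scaffold's reference
markers) otherwise.
"""

import argparse
import logging
from pathlib import Path

import pandas as pd

from cucsyn import io as cio
from cucsyn.pipeline import RunConfig, pct
from cucsyn.synteny import ReferenceMap, assign_chromosome
from cucsyn.vpcr import Assembly, classify_hits, virtual_pcr

logging.basicConfig(level=logging.INFO, format="%(message)s")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--sim", type=Path, default=Path("results/sim"))
    parser.add_argument("--consensus", type=Path,
                        default=Path("results/consensus"))
    parser.add_argument("--out", type=Path, default=Path("results/anchoring"))
    args = parser.parse_args()
    cfg = RunConfig()
    args.out.mkdir(parents=True, exist_ok=True)

    consensus = cio.read_map(args.consensus / "consensus_map.tsv")
    assembly = Assembly.from_fasta(args.sim / "scaffolds.fasta", "draft")
    primers = cio.read_primers(args.sim / "primers.tsv").set_index("marker_id")
    reference = ReferenceMap(pd.read_csv(args.sim / "reference_map.tsv", sep="\t"))

    hits_by_marker = {}
    for mid in sorted(consensus.marker_ids):
        row = primers.loc[mid]
        hits_by_marker[mid] = virtual_pcr(mid, row["primer_fwd"],
                                          row["primer_rev"], assembly, cfg.vpcr)
    classification = classify_hits(hits_by_marker)
    cio.write_hits([h for hits in hits_by_marker.values() for h in hits],
                   args.out / "vpcr_hits.tsv")
    pd.DataFrame(sorted(classification.items()),
                 columns=["marker_id", "class"]).to_csv(
        args.out / "classification.tsv", sep="\t", index=False)

    rows = []
    for gname, loci in consensus.groups.items():
        label = consensus.chromosome_labels.get(gname, "")
        for mid, pos in loci:
            a = assign_chromosome(mid, label or gname, pos,
                                  classification[mid], hits_by_marker[mid],
                                  reference)
            rows.append({
                "marker_id": mid, "group": gname, "source_chromosome": label,
                "source_cM": pos, "status": a.status,
                "target_chromosome": a.target_chromosome or "",
                "target_cM": "" if a.target_cM is None else a.target_cM,
                "evidence": a.evidence or "", "reason": a.reason,
            })
    anchored = pd.DataFrame(rows)
    anchored.to_csv(args.out / "anchored_markers.tsv", sep="\t", index=False)

    n = len(anchored)
    counts = {k: sum(1 for v in classification.values() if v == k)
              for k in ("unique", "multi_copy", "no_hit", "repeat_region")}
    n_assigned = int((anchored["status"] == "assigned").sum())
    n_direct = int((anchored["evidence"] == "direct_map").sum())
    print(f"consensus loci: {n}; virtual-PCR classes: {counts}")
    print(f"assigned to a target chromosome: {n_assigned} "
          f"({pct(n_assigned, n)}%), of which {n_direct} directly mapped")


if __name__ == "__main__":
    main()
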
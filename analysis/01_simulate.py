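#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds the 12-chromosome ancestral genome with its 401-marker panel, derives
the 7-chromosome genome by the default fusion/inversion scenario, fragments
it into draft scaffolds, and simulates the two mapping populations (91 F2
individuals, 80 F8 RILs) over the ancestral map.  Everything downstream
reads from results/sim/.
"""

import argparse
import logging
from pathlib import Path

import numpy as np

from cucsyn import io as cio
from cucsyn.linkage import PopulationType
from cucsyn.pipeline import RunConfig
from cucsyn.simulate import (apply_rearrangements, default_scenario,
                             fragment_scaffolds, make_reference_map,
                             marker_table, simulate_ancestral_genome,
                             simulate_population)

logging.basicConfig(level=logging.INFO, format="%(message)s")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/sim"))
    args = parser.parse_args()
    cfg = RunConfig(seed=args.seed)
    seeds = cfg.child_seeds(10)
    args.out.mkdir(parents=True, exist_ok=True)

    ancestral = simulate_ancestral_genome(seed=seeds[0], bp_per_cM=cfg.bp_per_cm)
    derived, truth = apply_rearrangements(ancestral, default_scenario())
    scaffold_set = fragment_scaffolds(derived, ancestral,
                                      mean_bp=cfg.scaffold_mean_bp,
                                      sigma=cfg.scaffold_sigma, seed=seeds[1])
    ref_df = make_reference_map(derived, scaffold_set,
                                n_reference_loci=cfg.n_reference_loci,
                                panel_fraction=cfg.direct_fraction,
                                seed=seeds[3])
    panel = marker_table(ancestral)

    rng = np.random.default_rng(seeds[4])
    in_f2 = rng.random(len(panel)) < cfg.f2_fraction
    in_ril = rng.random(len(panel)) < cfg.ril_fraction
    f2 = simulate_population(panel[in_f2], PopulationType.F2, cfg.n_f2,
                             seed=seeds[5], missing_rate=cfg.missing_rate)
    ril = simulate_population(panel[in_ril], PopulationType.RIL, cfg.n_ril,
                              seed=seeds[6], missing_rate=cfg.missing_rate)
    src_rng = np.random.default_rng(seeds[7])
    known = src_rng.random(len(panel)) < cfg.source_reference_fraction
    source_reference = panel.loc[known, ["marker_id", "chrom", "pos_cM"]]

    cio.write_fasta(scaffold_set.scaffolds, args.out / "scaffolds.fasta")
    scaffold_set.info.to_csv(args.out / "scaffold_truth.tsv", sep="\t", index=False)
    panel.to_csv(args.out / "markers.tsv", sep="\t", index=False)
    cio.write_primers(panel, args.out / "primers.tsv")
    ref_df.to_csv(args.out / "reference_map.tsv", sep="\t", index=False)
    source_reference.to_csv(args.out / "source_reference.tsv", sep="\t", index=False)
    cio.write_genotypes(f2, args.out / "genotypes_f2.tsv")
    cio.write_genotypes(ril, args.out / "genotypes_ril.tsv")
    truth.marker_truth.to_csv(args.out / "truth_markers.tsv", sep="\t", index=False)
    cio.write_json({"correspondence": truth.correspondence,
                    "correspondence_rev": truth.correspondence_rev,
                    "inversions": [list(t) for t in truth.inversions]},
                   args.out / "truth.json")

    n_scaff = len(scaffold_set.scaffolds)
    genome_mb = sum(len(s) for s in scaffold_set.scaffolds.values()) / 1e6
    print(f"ancestral genome: 12 chromosomes, {len(panel)} markers")
    print(f"derived genome: {len(derived.chrom_sequences)} chromosomes, "
          f"{n_scaff} scaffolds, {genome_mb:.2f} Mb")
    print(f"reference map: {len(ref_df)} loci "
          f"({(ref_df['marker_id'].str.startswith('mk')).sum()} panel markers)")
    print(f"populations: F2 n={cfg.n_f2} with {int(in_f2.sum())} markers; "
          f"RIL n={cfg.n_ril} with {int(in_ril.sum())} markers")
    print(f"wrote inputs to {args.out}")


if __name__ == "__main__":
    main()
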
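"""Map grid-cell diversity with and without bootstrap sample-bias correction.

Replicates every individual into all 10-arcminute cells within a 1-degree
circular neighborhood, keeps cells with >= 8 trees, and computes per-cell
allelic richness, Shannon index, Nei gene diversity, observed heterozygosity
and locally common alleles as means over 1,000 subsamples of 8 trees drawn
without replacement. Validates the correction against the closed-form
rarefaction expectation at g = 16 gene copies and writes per-cell tables and
ESRI ASCII rasters to results/grid/.
"""

import argparse
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from divgrid import (BootstrapConfig, GridSpec, allele_counts,  # noqa: E402
                     allelic_richness, cell_rarefaction_expectation,
                     diversity_raster, filter_cells, gridwide_bootstrap,
                     replicate_samples, validate_against_rarefaction)
from divgrid.simulate import cacao_like_scenario  # noqa: E402


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--B", type=int, default=1000)
    ap.add_argument("--min-trees", type=int, default=8)
    ap.add_argument("--out-dir", type=pathlib.Path,
                    default=pathlib.Path("results/grid"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    genotypes, passports, _, _ = cacao_like_scenario(args.seed)
    grid = GridSpec()
    assignment = replicate_samples(passports, grid, diameter=1.0)
    retained, stats = filter_cells(assignment, min_trees=args.min_trees)
    print(f"replication: {stats.n_placements_before} placements over "
          f"{stats.n_cells_before} cells; retained {stats.n_cells_after} cells "
          f"({stats.cell_retention:.0%}) holding "
          f"{stats.n_placements_after} placements ({stats.placement_retention:.0%})")

    config = BootstrapConfig(
        n_trees=args.min_trees, B=args.B, seed=args.seed,
        statistics=("allelic_richness", "shannon", "nei_diversity",
                    "obs_heterozygosity", "locally_common"))
    table = gridwide_bootstrap(retained, genotypes, config)
    raw = pd.Series({k: allelic_richness(allele_counts(genotypes, v))
                     for k, v in retained.cells.items()})
    raw.index = pd.MultiIndex.from_tuples(raw.index, names=["cell_col", "cell_row"])
    table["allelic_richness_uncorrected"] = raw
    table.to_csv(args.out_dir / "cell_diversity.csv")

    for stat in ("allelic_richness", "allelic_richness_uncorrected",
                 "locally_common", "nei_diversity"):
        r = diversity_raster(table, grid, stat)
        r.to_ascii(args.out_dir / f"{stat}.asc")

    analytic = cell_rarefaction_expectation(genotypes, retained.cells,
                                            2 * args.min_trees)
    analytic.index = pd.MultiIndex.from_tuples(analytic.index,
                                               names=["cell_col", "cell_row"])
    val_table = gridwide_bootstrap(
        retained, genotypes,
        BootstrapConfig(n_trees=args.min_trees, B=args.B, seed=args.seed,
                        statistics=("allelic_richness",)),
        locus_min_copies=2 * args.min_trees)
    slope, r = validate_against_rarefaction(val_table, analytic)
    print(f"bootstrap (B={args.B}) vs analytic rarefaction at g={2*args.min_trees}: "
          f"slope {slope:.3f}, Pearson r {r:.4f}")
    print(f"wrote cell table and rasters to {args.out_dir}")


if __name__ == "__main__":
    main()
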
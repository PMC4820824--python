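"""Gaussian graphical model over binding, composition and methylation.

Fits the full-partial-correlation network over ChIP, Input, GC%, CpG%,
mCpG% and mCpH% tracks of the simulated dataset and writes the edge list.
The direct ChIP-GC edge survives conditioning; marginal ChIP-CpG
association is explained away.
"""

from pathlib import Path

import seqbind as sb


ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    cfg = sb.SimConfig.ci_construction(seed=SEED, n_bins=100_000)
    genome = sb.simulate_genome(cfg)
    ft = sb.sequence_features(genome, genome.grid, k_set=(1,))
    sim = sb.simulate_chip_experiment(cfg, ft)
    meth = sb.simulate_methylation(cfg, genome)
    level = sb.bin_methylation_level(meth.sites, genome.grid, "CG")
    level_ch = sb.bin_methylation_level(meth.sites, genome.grid, "CH")
    tracks = {
        "chip": sim.chip,
        "input": sim.input,
        "gc": ft.gc_track(),
        "cpg": ft.cpg_track(),
        "mcpg": sb.methylation_density(level, ft, "CpG"),
        "mcph": sb.methylation_density(level_ch, ft, "CpH"),
    }
    g = sb.fit_ggm(tracks)
    edges = g.edge_frame().sort_values("weight", ascending=False)
    edges.to_csv(ROOT / "ggm_edges.tsv", sep="\t", index=False)
    print(f"GGM over {len(g.nodes)} tracks, {g.n_bins} complete-case bins")
    print(edges.to_string(index=False, float_format=lambda v: f"{v:+.3f}"))


if __name__ == "__main__":
    main()
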
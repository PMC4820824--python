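"""Generate the synthetic study dataset with planted ground truth.

Simulates a two-chromosome genome with autocorrelated GC content and
GC-coupled CpG density, ChIP/Input/MNase fragment channels whose
enrichment sits in GC-rich peak runs at a background scaling factor of
4.41, per-cytosine methylation calls (70% background, hypomethylated
promoter islands, hypermethylated distal islands), and a WT/KO expression
table whose fold changes depend on promoter binding and gene length.

Writes FASTA, BED, bedGraph, cytosine-report and TSV files under
scratch/sim/ (bulky, regenerated on demand) and prints the planted
parameters.
"""

from pathlib import Path

import numpy as np

import seqbind as sb
from seqbind.ioutils import write_bed, write_bedgraph, write_fasta
from seqbind.methylation import write_cytosine_report
from seqbind.simulate import with_options

OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = with_options(
        sb.SimConfig(seed=SEED, n_chroms=2, chrom_length=1_500_000),
        binding_effect=-0.3,
        length_effect=-0.2,
    )
    genome = sb.simulate_genome(cfg)
    ft = sb.sequence_features(genome, genome.grid, k_set=(1, 2))
    sim = sb.simulate_chip_experiment(cfg, ft)
    genes = sb.simulate_genes(cfg, genome.grid)
    meth = sb.simulate_methylation(cfg, genome, genes)
    ses = sb.ses_scale(sim.chip, sim.input)
    enr = sb.enrichment_track(sim.chip, sim.input, ses.upsilon)
    expr = sb.simulate_expression(cfg, enr, genes, sim.truth)

    write_fasta(genome.sequences(), OUT / "genome.fa")
    write_bedgraph(sim.chip, OUT / "chip.bedgraph")
    write_bedgraph(sim.input, OUT / "input.bedgraph")
    write_bedgraph(sim.mnase, OUT / "mnase.bedgraph")
    write_bed(sim.peaks, OUT / "peaks.bed")
    write_bed(meth.cgis, OUT / "cgis.bed")
    write_cytosine_report(meth.sites, OUT / "cytosine_report.tsv")
    genes.to_csv(OUT / "genes.tsv", sep="\t", index=False)
    expr.expression.to_csv(OUT / "expression.tsv", sep="\t", index=False)
    expr.annotation.to_csv(OUT / "go_annotation.tsv", sep="\t", index=False)
    mapp = sb.simulate_mappability(cfg, genome.chrom_sizes)
    write_bedgraph(mapp, OUT / "mappability.bedgraph")

    print(f"genome: {cfg.n_chroms} x {cfg.chrom_length/1e6:.1f} Mb, "
          f"{genome.grid.n_bins} bins of {cfg.bin_width} bp")
    print(f"planted upsilon_true = {cfg.upsilon_true}, "
          f"peak bins = {sim.truth.peak_bins.sum()} "
          f"({100*sim.truth.peak_bins.mean():.1f}% of genome)")
    print(f"CpG sites (both strands): {len(meth.sites.subset('CG'))}; "
          f"genes: {len(genes)}; GO terms: {cfg.n_go_terms}")
    print(f"wrote {len(list(OUT.iterdir()))} files to {OUT}")


if __name__ == "__main__":
    main()
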
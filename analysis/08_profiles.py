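"""Anchor-aligned signal maps around TSSs and peak centres.

Aligns the MNase and enrichment tracks in windows around gene TSSs
(ordered by expression) and peak centres (ordered by peak width),
pixelates the matrices for display, and writes quartile median profiles.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import seqbind as sb


ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    cfg = sb.SimConfig(seed=SEED, n_chroms=2, chrom_length=1_500_000)
    genome = sb.simulate_genome(cfg)
    ft = sb.sequence_features(genome, genome.grid, k_set=(1,))
    sim = sb.simulate_chip_experiment(cfg, ft)
    ses = sb.ses_scale(sim.chip, sim.input)
    enr = sb.enrichment_track(sim.chip, sim.input, ses.upsilon)
    genes = sb.simulate_genes(cfg, genome.grid)
    ex = sb.simulate_expression(cfg, enr, genes, sim.truth)
    fpkm = ex.expression.set_index("gene")["fpkm_wt"]

    tss_anchors = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "pos": genes["tss"],
            "strand": genes["strand"],
            "score": np.log2(fpkm.loc[genes["gene"]].to_numpy() + 1),
        }
    )
    centers = (sim.peaks["start"] + sim.peaks["end"]) // 2
    peak_anchors = pd.DataFrame(
        {
            "chrom": sim.peaks["chrom"],
            "pos": centers,
            "strand": "+",
            "score": (sim.peaks["end"] - sim.peaks["start"]).astype(float),
        }
    )

    for name, anchors, signal, hw in (
        ("tss_mnase", tss_anchors, sim.mnase, 4000),
        ("peak_enrichment", peak_anchors, enr, 4000),
    ):
        mat = sb.align_signal(anchors, signal, half_width=hw)
        px = sb.pixelate(mat)
        scratch = ROOT.parent / "scratch"
        scratch.mkdir(exist_ok=True)
        np.savetxt(scratch / f"profile_{name}_pixels.tsv", px, delimiter="\t", fmt="%.5g")
        prof = sb.quartile_median_profiles(mat)
        pd.DataFrame(
            prof.T, columns=[f"q{i+1}" for i in range(4)]
        ).assign(offset_bp=mat.offsets_bp).to_csv(
            ROOT / f"profile_{name}_quartiles.tsv", sep="\t", index=False
        )
        center = prof.shape[1] // 2
        print(f"{name}: {mat.matrix.shape[0]} anchors, pixelated to {px.shape}; "
              f"top-quartile centre value {prof[3][center]:.2f} "
              f"(edges {np.nanmean([prof[3][0], prof[3][-1]]):.2f})")


if __name__ == "__main__":
    main()
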
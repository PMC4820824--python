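"""Dissect GC/CpG confounding of the binding signal.

On the conditional-independence construction (enrichment a linear
function of window GC% only), measures the marginal ChIP~CpG%
correlation, the partial correlations controlling GC% or CpG%, the
conditional enrichment map over the (GC%, CpG%) plane, the signal
autocorrelation half-width, and the ChIP x MNase cross-correlation.
"""

import json
from pathlib import Path



import seqbind as sb

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    cfg = sb.SimConfig.ci_construction(seed=SEED, n_bins=100_000)
    genome = sb.simulate_genome(cfg)
    ft = sb.sequence_features(genome, genome.grid, k_set=(1,))
    sim = sb.simulate_chip_experiment(cfg, ft)
    chip, gc, cpg = sim.chip, ft.gc_track(), ft.cpg_track()

    r_marg, n = sb.pearson_correlation(chip, cpg)
    r_cpg_gc, _ = sb.partial_correlation(chip, cpg, [gc])
    r_gc_cpg, _ = sb.partial_correlation(chip, gc, [cpg])
    r_construction = sb.expected_partial_r_gc(sim.truth, ft)

    cmap = sb.conditional_enrichment_map(
        ft, chip.normalized(), gc_res=0.04, cpg_res=0.013, min_count=50
    )
    cmap.to_frame().to_csv(ROOT / "conditional_map.tsv", sep="\t", index=False)

    acf = sb.autocorrelation_hwhm(chip, max_lag=60)
    xc = sb.cross_correlation(sim.chip, sim.mnase, max_offset=20)

    out = {
        "n_bins": n,
        "marginal_r_chip_cpg": r_marg,
        "partial_r_chip_cpg_given_gc": r_cpg_gc,
        "partial_r_chip_gc_given_cpg": r_gc_cpg,
        "construction_partial_r_chip_gc": r_construction,
        "acf_hwhm_bp": acf.hwhm_bp,
        "xcorr_argmax_bp": xc.argmax_bp,
        "xcorr_max_r": xc.r_max,
    }
    with open(ROOT / "confounding.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"marginal r(ChIP, CpG%) = {r_marg:.3f} over {n} windows")
    print(f"partial r(ChIP, CpG% | GC%) = {r_cpg_gc:+.4f}  "
          "(conditional independence holds by construction)")
    print(f"partial r(ChIP, GC% | CpG%) = {r_gc_cpg:.3f} "
          f"(construction value {r_construction:.3f})")
    print(f"ChIP autocorrelation HWHM = {acf.hwhm_bp:.0f} bp; "
          f"ChIP x MNase cross-correlation peaks at {xc.argmax_bp} bp "
          f"(r = {xc.r_max:.3f})")


if __name__ == "__main__":
    main()
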
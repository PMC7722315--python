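"""Both-flank RBP binding, inverted-Alu pairs, and the knockdown response of
flanked circRNAs."""

from runcommon import RUNDIR, config, publish
from circscreen.pipeline import stage_flanks

if __name__ == "__main__":
    out = stage_flanks(config(), RUNDIR)
    for name, numbered in (("flank_enrichment.tsv", "04_flank_enrichment.tsv"),
                           ("iralu_flags.tsv", "04_iralu_flags.tsv"),
                           ("kd_comparison.tsv", "04_kd_comparison.tsv")):
        publish(name, numbered)
    best = out["flank_enrichment"].sort_values("fold", ascending=False).iloc[0]
    print(f"strongest both-flank enrichment: {best['rbp']} "
          f"({best['fold']:.1f}x, chi-square p = {best['p']:.2g})")
    print(out["kd_comparison"]
          [["subset", "test", "n_circ", "relative_change", "p"]].to_string(index=False))
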
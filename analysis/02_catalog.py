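"""Build the consensus circRNA catalog and its highly expressed top set."""

from runcommon import RUNDIR, config, publish
from circscreen.pipeline import stage_catalog

if __name__ == "__main__":
    table = stage_catalog(config(), RUNDIR)
    out = publish("catalog.tsv", "02_circRNA_catalog.tsv")
    top = table[table["in_top_set"]]
    print(f"{len(table)} consensus circRNAs; top set of {len(top)} "
          f"(min {top['BSJ_reads'].min()} BSJ reads); table -> {out}")
    print(top[["circRNA_ID", "host_gene", "BSJ_reads", "relative_ratio",
               "exonic_length", "N_exons"]].to_string(index=False))
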
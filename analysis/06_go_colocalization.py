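"""GO enrichment of circ-exon-binding RBPs and circRNA-RBP co-localization."""

import json
import os

from runcommon import RUNDIR, config, publish
from circscreen.pipeline import stage_enrich, stage_report

if __name__ == "__main__":
    out = stage_enrich(config(), RUNDIR)
    report = stage_report(config(), RUNDIR)
    for name, numbered in (("go_enrichment.tsv", "06_go_enrichment.tsv"),
                           ("colocalization.tsv", "06_colocalization.tsv"),
                           ("report.json", "06_report.json")):
        publish(name, numbered)
    coloc = out["colocalization"].iloc[0]
    print(f"{coloc['colocalized_pct']:.1f}% of {int(coloc['n_resolved'])} resolved "
          "circRNA-RBP interactions share a subcellular compartment")
    if len(out["go_enrichment"]):
        print(out["go_enrichment"].sort_values("p").to_string(index=False))
    print("full run report:", json.dumps(report, indent=1, sort_keys=True))
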
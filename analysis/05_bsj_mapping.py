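"""Map short eCLIP reads across backsplice junctions and call bound junctions."""

from runcommon import RUNDIR, config, publish
from circscreen.pipeline import stage_bsjmap

if __name__ == "__main__":
    calls = stage_bsjmap(config(), RUNDIR)
    out = publish("bsj_junction_calls.tsv", "05_bsj_junction_calls.tsv")
    called = calls[calls["called"]]
    print(f"{len(called)}/{len(calls)} junctions called "
          f"(>=10 dedup reads per IP replicate, log2FC >= 3 vs input) -> {out}")
    print(called.to_string(index=False))
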
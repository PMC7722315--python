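"""Shared run-directory convention for the numbered analysis drivers.

Raw simulated inputs and full stage outputs live under scratch/analysis_run
(regenerated on demand); the summary tables each driver reports are copied
into results/.
"""

import os
import shutil

from circscreen.pipeline import desk_scale_config

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
RUNDIR = os.path.join(ROOT, "scratch", "analysis_run")
RESULTS = os.path.join(ROOT, "results")
SEED = 0


def config():
    return desk_scale_config(seed=SEED)


def publish(name: str, numbered: str) -> str:
    """Copy a stage output table from the run directory into results/."""
    os.makedirs(RESULTS, exist_ok=True)
    src = os.path.join(RUNDIR, name)
    dst = os.path.join(RESULTS, numbered)
    shutil.copyfile(src, dst)
    return dst
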
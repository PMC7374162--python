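"""Shared locations for the analysis drivers.

Large intermediates (count tables, AMF matrices, the frozen model) live under
scratch/; small summary tables the narrative cares about go to results/.
Every driver is re-runnable on its own: it rebuilds what it needs from the
scripts before it if the scratch artifacts are absent.
"""

import pathlib

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort_run"
RESULTS = ROOT / "results"
SEED = 7

SCRATCH.mkdir(parents=True, exist_ok=True)
RESULTS.mkdir(parents=True, exist_ok=True)
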
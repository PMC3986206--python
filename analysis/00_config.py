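"""Shared settings for the numbered analysis scripts.

Every script can be run on its own (later ones expect the outputs of
earlier ones under results/). The panel is synthetic: a structured barley-
like collection drawn from the generator's default study conditions.
"""

from pathlib import Path

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

for d in (RESULTS, DATA):
    d.mkdir(parents=True, exist_ok=True)
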
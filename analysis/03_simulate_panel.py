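#!/usr/bin/env python
"""Simulate the 18-sequence fluorescence panel in the strand-exchange geometry.

Generates one donor-emission trace per panel sequence (0.5-s sampling
over 30 min, recover-up geometry, mild readout noise) whose plateau
follows the generative model g = s_het + (1 - s_het) N_{8,<2}/13, and
writes the ground-truth manifest.  Full traces go under scratch/ (they
are bulky intermediates); the manifest of true plateaus goes under
results/.
"""

import json
from pathlib import Path

from recascan.experiments import default_panel
from recascan.fret import PanelSignalModel, SimConfig, simulate_panel
from recascan.io import write_trace_tsv

ROOT = Path(__file__).resolve().parents[1]
TRACE_DIR = ROOT / "scratch" / "traces"
OUT = ROOT / "results"

SEED = 7
SIGMA = 0.5  # a.u. readout noise per 0.5-s sample


def main() -> None:
    panel = default_panel()
    config = SimConfig(geometry="recover-up", sigma=SIGMA, seed=SEED)
    traces, manifest = simulate_panel(panel, PanelSignalModel(), config)
    TRACE_DIR.mkdir(parents=True, exist_ok=True)
    for name, trace in traces.items():
        safe = name.replace("/", "_").replace("'", "p").replace(" ", "_")
        write_trace_tsv(trace, TRACE_DIR / f"{safe}.tsv")
        manifest[name]["file"] = f"{safe}.tsv"
    OUT.mkdir(exist_ok=True)
    (OUT / "panel_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print(
        f"Simulated {len(traces)} traces ({len(next(iter(traces.values())).times)} "
        f"samples each, sigma={SIGMA}) into {TRACE_DIR}; manifest in results/."
    )


if __name__ == "__main__":
    main()
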
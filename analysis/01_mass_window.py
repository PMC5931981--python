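#!/usr/bin/env python
"""Theoretical m/z of the myo-inositol monophosphate [M-H]- ion.

The kinase assay's product identification relies on a narrow extracted-ion
LC-MS window (m/z 259.0211-259.0237).  This driver computes the
monoisotopic neutral mass of C6H13O9P and the deprotonated-ion m/z and
checks that the ion falls inside that window.

Writes results/mass_window.json.
"""

import json
from pathlib import Path

from ppisig.model_io import monoisotopic_mass, mz_minus_h

WINDOW = (259.0211, 259.0237)
FORMULA = "C6H13O9P"

out_dir = Path(__file__).resolve().parents[1] / "results"
out_dir.mkdir(exist_ok=True)

neutral = monoisotopic_mass(FORMULA)
mz = mz_minus_h(FORMULA)
inside = WINDOW[0] <= mz <= WINDOW[1]

print(f"monoisotopic mass of {FORMULA}: {neutral:.4f} Da")
print(f"[M-H]- m/z:                  {mz:.4f}")
print(f"inside window {WINDOW}: {inside}")

(out_dir / "mass_window.json").write_text(json.dumps({
    "formula": FORMULA,
    "neutral_monoisotopic_mass_da": round(neutral, 6),
    "mz_minus_h": round(mz, 6),
    "window": WINDOW,
    "inside_window": inside,
}, indent=2) + "\n")
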
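#!/usr/bin/env python
"""Generate the study's synthetic datasets.

Writes the imaging fixture (3 pups x 2 cohorts: a broad E13.5-like and a
compact E15.5-like isochronic cohort) and the expression panel (birthdates
E12-E15 x stages AP/N1d/N4d plus adult deep- and superficial-layer
conditions) under scratch/data/.  All downstream scripts read from there.
"""

from pathlib import Path

from isochron.synthgen import make_fixtures

SEED = 0
OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"

if __name__ == "__main__":
    paths = make_fixtures(SEED, OUT)
    print(f"seed {SEED}")
    for key, p in paths.items():
        print(f"  {key}: {p}")
    print("done: imaging tables + Matrix Market expression panel written")
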
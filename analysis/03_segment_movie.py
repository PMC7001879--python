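#!/usr/bin/env python
"""Footprint recovery by sparse NMF on the default synthetic movie.

Renders a 256 x 256 movie (~1,200 frames) with 20 planted dendrites,
factorizes it with K = 30, matches components to ground truth by Hungarian
assignment on spatial cosine similarity, and reports how many planted
footprints are recovered at cosine >= 0.8.  Writes
results/segmentation_recovery.json.
"""

import json
from pathlib import Path

from tuftpipe.studies import segmentation_recovery_study


def main():
    res = segmentation_recovery_study(seed=0)
    Path("results").mkdir(exist_ok=True)
    Path("results/segmentation_recovery.json").write_text(json.dumps(res, indent=2))
    print(f"matched {res['n_matched_08']}/{res['n_planted']} planted footprints "
          f"at cosine >= 0.8 (median {res['median_cosine']:.3f}); "
          f"{res['n_components_retained']} components retained; "
          f"objective monotone: {res['objective_monotone']}")


if __name__ == "__main__":
    main()
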
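#!/usr/bin/env python
"""Write a complete synthetic demo input set next to this script.

Creates markers.tsv (79 screened SSR loci on a Chr19-like chromosome) and
one bedGraph per feature track. All values are synthetic. Run once before
using config.yaml:

    python examples/make_inputs.py
"""

from pathlib import Path

import numpy as np

from hdnacap.genome import write_feature_track, write_marker_panel
from hdnacap.synthetic import make_demo_chromosome, make_demo_panel, make_demo_tracks

HERE = Path(__file__).parent


def main() -> None:
    chrom = make_demo_chromosome()
    rng = np.random.default_rng(2021)
    write_marker_panel(make_demo_panel(chrom, 79, rng), HERE / "markers.tsv")
    for kind, track in make_demo_tracks(chrom, rng).items():
        write_feature_track(track, HERE / f"{kind}.bedgraph")
    print(f"inputs written to {HERE}")


if __name__ == "__main__":
    main()
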
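#!/usr/bin/env python
"""%-of-maximum response surfaces over TIF1γ/Smad4 ratio × duration.

Finding: the transcription-competent pS24n pool is maximal at low
TIF1γ/Smad4 ratios, whereas the alternative pSmad2–TIF1γ transcription
complex needs high ratios to approach its maximum — the two outputs
partition the (ratio, duration) plane into complementary regimes.
"""

from pathlib import Path

import numpy as np

from smadtif.scans import response_surface

OUT = Path(__file__).resolve().parents[1] / "results"

RATIOS = [0.0, 0.1, 0.2, 0.5, 1.0]
DURATIONS = [900.0, 3600.0, 14400.0, 86400.0]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for name in ("pS24n", "pS2nTIF1g"):
        res = response_surface(RATIOS, DURATIONS, name)
        res.to_csv(OUT / f"surface_{name}.csv")
        z = res.meta["surface"]
        i, j = np.unravel_index(np.argmax(z), z.shape)
        print(f"{name}: maximum at ratio {RATIOS[i]:.1f}, "
              f"duration {DURATIONS[j] / 3600:.2f} h")
        with np.printoptions(precision=1, suppress=True):
            print(z)
    print(f"wrote surfaces to {OUT}")


if __name__ == "__main__":
    main()
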
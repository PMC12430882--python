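"""Reading and writing spectral cubes and 16-bit RGB images.

Round-trips a reflectance cube through both on-disk formats (ENVI header +
band-sequential binary, and the compressed container with JSON sidecar) and
an RGB render through 16-bit PNG.
"""

import tempfile
from pathlib import Path

import numpy as np

from specrec import (CameraResponse, SceneParams, builtin_conditions,
                     render_pair, sample_reflectance_field)
from specrec.io import read_cube, read_rgb, write_cube, write_rgb

params = SceneParams(image_size=16, n_bands=8)
pair = render_pair(sample_reflectance_field(params, 3),
                   builtin_conditions()[4],
                   CameraResponse.gaussian(params.grid))

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    for name in ("cube.hdr", "cube.npz"):
        write_cube(pair.reflectance_gt, tmp / name)
        restored = read_cube(tmp / name)
        exact = np.array_equal(restored.values, pair.reflectance_gt.values)
        print(f"{name}: read back bit-exact = {exact}, "
              f"{restored.grid.band_count} bands on "
              f"[{restored.grid.band_centers[0]:.0f}, "
              f"{restored.grid.band_centers[-1]:.0f}] nm")
    write_rgb(pair.sample_rgb, tmp / "sample.png")
    loaded = read_rgb(tmp / "sample.png")
    worst = np.abs(loaded.values - pair.sample_rgb.values).max()
    print(f"sample.png: 16-bit round trip, max abs error {worst:.2e} "
          f"(quantisation step {pair.sample_rgb.values.max() / 65535:.2e})")
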
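"""Write and read depth frames in the two supported file dialects.

Shows the plain-text matrix dump (one line per pixel row, integer mm) and
the 16-bit PGM (one grey level per mm), plus the close-shot depth window.
"""

import tempfile
from pathlib import Path

import numpy as np

from spherecut import (
    DepthFrame,
    SpheroidFruit,
    Scene,
    depth_window,
    make_sensor,
    read_pgm,
    read_text_frame,
    render_depth,
    write_pgm,
    write_text_frame,
)

sensor = make_sensor("F200", noise_sd=0.0, dropout_p=0.0)
scene = Scene([SpheroidFruit([0.0, 0.0, 400.0], 50.0, 55.0)], sensor,
              backdrop_depth=900.0)
frame, _ = render_depth(scene, seed=0)

out = Path(tempfile.mkdtemp())
write_text_frame(frame, out / "frame.txt")
write_pgm(frame, out / "frame.pgm")

back_txt = read_text_frame(out / "frame.txt")
back_pgm = read_pgm(out / "frame.pgm")
assert np.array_equal(back_txt.values, back_pgm.values)
print(f"wrote {out / 'frame.txt'} and frame.pgm; both re-read identically")
print(f"valid pixels before windowing: {back_pgm.n_valid}")

windowed = depth_window(back_pgm, 160.0, 700.0)
print(f"valid pixels in the 160-700 mm close-shot window: {windowed.n_valid}")
survivors = windowed.values[windowed.values > 0]
print(f"surviving depth range: [{survivors.min():.0f}, {survivors.max():.0f}] mm")

# The 900 mm backdrop wall fills the raw frame but disappears after depth
# windowing, leaving only the fruit's ~3500-pixel cloud — the rapid
# foreground/background elimination that makes close-shot recognition cheap.
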
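"""Generate the three stimulus families as 5-bit display frames.

Renders a drifting square-wave grating, one receptive-field bar sweep, and
the distance/angular-size schedule of a looming object.
"""

import numpy as np

from goggleskit import stimuli
from goggleskit.fieldmap import DisplayMapping

mapping = DisplayMapping()

spec = stimuli.GratingSpec(wavelength_px=20, tf_hz=1.0, contrast_pair=(24, 6),
                           window=(0, 0, 80), duration_s=1.0, fps=30)
frames = stimuli.grating_frames(spec, mapping)
print(f"grating: {frames.shape[0]} frames of {frames.shape[1]}x{frames.shape[2]} px, "
      f"{stimuli.sf_px_to_cpd(spec.wavelength_px, mapping):.4f} cycles/deg, "
      f"{stimuli.michelson_contrast(spec.contrast_pair):.0f}% Michelson contrast")

bars, meta = stimuli.bar_sweep_stimulus(grid_index=12, mapping=mapping, fps=30)
print(f"bar sweep: cell {meta['grid_index']} centered at {meta['cell_center_deg']} deg, "
      f"{meta['cell_width_deg']:.1f} deg wide, directions {meta['directions']}")

loom = stimuli.loom_schedule(stimuli.LoomSpec(object_diameter_m=0.5))
print(f"loom: {loom['duration_s']:.3f} s approach, angular diameter grows "
      f"{loom['angular_diameter_deg'][0]:.1f} -> {loom['angular_diameter_deg'][-1]:.1f} deg")

# warp a perspective-rendered view onto the circular angle-linear display
x = np.linspace(-1, 1, 221)
scene = 100 + 50 * np.sin(3 * np.pi * x[None, :]) * np.cos(2 * np.pi * x[:, None])
display_img = stimuli.warp_viewport(scene, planar_fov_deg=100, mapping=mapping, out_size=221)
print(f"warped viewport: {display_img.shape} px display image (center preserved: "
      f"{np.isclose(display_img[110, 110], scene[110, 110])})")
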
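"""Binocular visual-field coverage of a two-eyepiece headset.

Builds the angle-linear display model (1.57 px/deg, 140-degree FOV per
eye), places the two eyepiece caps at +/-45 degrees azimuth and 15 degrees
pitch, and prints the coverage summary.
"""

from goggleskit import fieldmap
from goggleskit.fieldmap import DisplayMapping

mapping = DisplayMapping(resolution=1.57, half_fov=70)
print(f"Nyquist limit: {fieldmap.nyquist_cpd(mapping)} cycles/deg "
      "(mouse acuity is ~0.5, so the display out-resolves the mouse eye)")

left = fieldmap.eyepiece_footprint(DisplayMapping(axis_azimuth=-45, axis_elevation=15))
right = fieldmap.eyepiece_footprint(DisplayMapping(axis_azimuth=45, axis_elevation=15))
m = fieldmap.binocular_metrics(left, right)
print(f"horizontal extent: {m['horizontal_extent_deg']:.1f} deg "
      f"(along the horizontal meridian at {m['meridian_elevation_deg']:.0f} deg elevation)")
print(f"vertical extent:   {m['vertical_extent_deg']:.1f} deg "
      f"({left.boundary[:, 1].min():.0f} to {left.boundary[:, 1].max():.0f} deg elevation)")
print(f"binocular overlap: {m['overlap_deg']:.1f} deg along that meridian "
      f"({m['intersection_sr']:.2f} sr full 2-D intersection)")

# planar coordinates for a visual-field plot (Winkel tripel projection)
xy = fieldmap.project_winkel_tripel(fieldmap.mouse_fov_ellipse("right").boundary)
print(f"mouse-eye FOV ellipse projects to x in [{xy[:, 0].min():.2f}, {xy[:, 0].max():.2f}]")
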
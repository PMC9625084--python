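"""Detect particles in ideal heat maps and link them over time.

Uses renderer-produced truth maps as a stand-in for network output (the
decoder is the same either way), detects two crossing particles in every
frame, and shows that the dry-mass term in the linking cost keeps their
identities straight through the crossing.
"""

import numpy as np

from holomass import (
    OpticalConfig,
    Particle,
    Scene,
    detections_from_maps,
    link_tracks,
    render_truth_maps,
)

cfg = OpticalConfig()
pitch = cfg.pixel_pitch_um

per_frame = []
for f in range(21):
    light = Particle.from_dry_mass((10 + f) * pitch, 30 * pitch, 700.0, 2.0, 50.0, cfg)
    heavy = Particle.from_dry_mass((30 - f) * pitch, 30 * pitch, 900.0, 4.0, 400.0, cfg)
    scene = Scene([light, heavy], cfg, image_shape=(64, 64))
    maps = render_truth_maps(scene).stack()
    per_frame.append(detections_from_maps(maps, frame_index=f))

tracks = link_tracks(per_frame, pitch)
print(f"{len(tracks)} tracks from {len(per_frame)} frames "
      "(two particles crossing at frame 10)")
for t in tracks:
    masses = [d.mass_pg for d in t.detections]
    x0, x1 = t.detections[0].x_px, t.detections[-1].x_px
    print(
        f"  track {t.id}: {len(t.detections)} frames, "
        f"x {x0:.1f} -> {x1:.1f} px, mass {np.mean(masses):.0f} pg "
        f"(spread {np.ptp(masses):.2f} pg: identity preserved)"
    )
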
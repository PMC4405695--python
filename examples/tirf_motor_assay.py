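"""Single-molecule TIRF assay: motors per µm, percent moving, lifespans.

Simulates motor spots on microtubule filaments for two conditions —
"control" and "inhibited" (lower landing density and moving fraction,
emulating a regulator that blocks the motor's microtubule binding) —
renders image stacks, and runs the full detect -> link -> metrics
pipeline.
"""

import numpy as np

from vesitrack import (detect_spots, link_spots, motor_assay_report,
                       render_spot_stack, simulate_motor_field)

N_FIELDS = 5   # one condition = several imaged fields, like a real session


def run_condition(name, density, moving_fraction, seed0):
    densities, moving, spans, n_tracks = [], [], [], 0
    for k in range(N_FIELDS):
        seed = seed0 + 100 * k
        field = simulate_motor_field(
            mt_total_length=80.0, density=density,
            moving_fraction=moving_fraction, speed=0.5, lifespan_mean=2.0,
            n_frames=60, frame_interval=0.041, seed=seed,
            image_shape=(384, 384), min_spot_separation=0.4)
        stack = render_spot_stack(field.spots, field.mask.labels.shape,
                                  field.mask.pixel_size, n_frames=60,
                                  psf_sigma=1.0, amplitude=200.0,
                                  background=10.0, noise_sd=2.0, seed=seed + 1)
        spots = detect_spots(stack, intensity_threshold=60.0, min_separation=3,
                             pixel_size=field.mask.pixel_size)
        tracks = link_spots(spots, max_disp=0.3, max_gap=1,
                            frame_interval=0.041)
        rep = motor_assay_report(tracks, spots, field.mask)
        densities.append(rep.motors_per_um)
        moving.append(rep.percent_moving)
        spans.append(rep.median_lifespan)
        n_tracks += rep.n_motors
    res = (float(np.mean(densities)), float(np.mean(moving)),
           float(np.median(spans)))
    print(f"{name}: {res[0]:.3f} motors/µm, {res[1]:.2f}% moving, "
          f"median lifespan {res[2]:.2f} s "
          f"({n_tracks} tracks over {N_FIELDS} fields)")
    return res


ctrl = run_condition("control  ", density=0.32, moving_fraction=0.05, seed0=10)
inhib = run_condition("inhibited", density=0.22, moving_fraction=0.02, seed0=17)

print(f"""
Density ratio inhibited/control: {inhib[0] / ctrl[0]:.2f}
Moving motors are tracks with mean speed > 0.12 µm/s, net displacement
> 0.2 µm, and duration > 0.9 s; the denominator keeps every track, so
the large short-lived immobile pool dilutes the percentage exactly as
it does in a real streaming TIRF experiment.""")
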
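"""Simulate one subject and measure its tumor T2* before and after contrast.

Builds a leg-cross-section phantom (tumor mean T2* 14.2 ms at 7 T), applies
iron-oxide contrast calibrated to shorten the tumor mean to ~10.2 ms,
simulates noisy acquisitions, fits the parametric map and runs the
muscle-referenced measurement.  The two printed means demonstrate the
contrast-induced shortening the measurement is designed to detect.
"""

from relaxrepro import (
    GeometryConfig,
    TissueParams,
    apply_contrast,
    fit_map,
    make_phantom,
    measure_tumor,
    protocol_preset,
    simulate_acquisition,
)

tissue = {
    "tumor": TissueParams(T_mean=14.2, T_sd=2.1, S0_mean=100, A_mean=5),
    "muscle": TissueParams(T_mean=14.0, T_sd=1.1, S0_mean=80, A_mean=4),
    "bone": TissueParams(T_mean=0.8, T_sd=0.1, S0_mean=15, A_mean=1),
}
phantom, roi = make_phantom(GeometryConfig(), tissue, seed=1)
# rate addition 1/10.21 - 1/14.2 moves the tumor mean to the post-contrast value
post = apply_contrast(phantom, delta_R_mean=1 / 10.21 - 1 / 14.2, seed=2)

protocol = protocol_preset(7, "T2star", matrix=(64, 64), n_slices=3)
for label, ph in (("pre ", phantom), ("post", post)):
    series = simulate_acquisition(ph, protocol, snr=50, seed=3)
    pmap = fit_map(series, mask=roi.tumor_mask)
    m = measure_tumor(series, pmap, roi)  # 7 T default: mask below 7% of muscle
    print(f"{label}-contrast tumor mean T2*: {m.mean_T:5.2f} ms  "
          f"({m.n_voxels_retained}/{m.n_voxels_total} voxels retained)")
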
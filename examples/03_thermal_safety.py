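"""Coupled optical-thermal run: how much does the light heat the tissue?

Feeds the absorbed optical power Q_r = mu_a * phi from the 810 nm diffusion
solution into the steady Pennes bioheat equation (blood perfusion sink,
metabolic heat, convective cooling of the scalp to 25 °C air) and reports the
temperature rise over the no-light baseline, per tissue.
"""

import tnirsim as t

phantom = t.build_phantom()
props = t.assign_properties(phantom, 810)
field = t.solve_diffusion(phantom, props, t.SourceSpec())  # 0.5 W at 810 nm
Qr = t.heat_source(props.mu_a, field)
temps = t.solve_steady_bioheat(phantom, props, Qr, t.SurfaceBoundary())
summary = t.temperature_rise_summary(temps)

print("temperature rise over the no-source baseline (°C):")
for tissue, stats in summary["per_tissue"].items():
    print(
        f"  {tissue:<13s} max dT = {stats['max_dT']:.4f}  "
        f"mean dT = {stats['mean_dT']:.5f}  "
        f"volume-avg T = {stats['volume_avg_T']:.3f}"
    )
print(f"  scalp-surface maximum dT = {summary['surface_max_dT']:.3f} °C")

# The perfusion sink clamps deep brain tissue near the perfusion-metabolic
# equilibrium 37 + Q_met/(rho_b*omega_b*c_b) = 37.0345 °C.  Heating is
# concentrated in the scalp/skull under the source; with the full 0.5 W
# injected, the superficial peak rise is on the order of degrees while the
# gray matter stays within ~0.15 °C.
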
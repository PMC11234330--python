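"""Dimensionless numbers of the biofilm flow channel.

Computes the mean velocity, Reynolds and Peclet numbers for the 5 mm x
15 um channel at the two study flow rates, plus the Stokes settling
velocity of the tracer microspheres.
"""

from trapflow.geometry import (
    ChannelSpec,
    WATER,
    mean_velocity,
    peclet_number,
    reynolds_number,
    settling_velocity,
    stokes_einstein_diffusivity,
)

channel = ChannelSpec()
for rate in (0.5, 3.0):
    U = mean_velocity(rate, channel)
    re_dh = reynolds_number(rate, channel, WATER, "hydraulic_diameter")
    re_fh = reynolds_number(rate, channel, WATER, "feature_height")
    D = stokes_einstein_diffusivity(0.5)  # 1 um tracer/bacterium
    pe = peclet_number(U, channel.height, D)
    print(f"flow rate {rate} uL/min: U = {U:.0f} um/s, "
          f"Re(hydraulic) = {re_dh:.4f}, Re(feature) = {re_fh:.4f}, "
          f"Pe = {pe:.0f}")
print(f"tracer settling velocity (2 um, 1.3 g/mL): "
      f"{settling_velocity(2.0, 1.3):.2f} um/s")
# Re << 1 confirms creeping flow at both rates; Pe >> 1 means transport
# is advection-dominated; settling ~0.65 um/s empties the 15 um channel
# height in ~20 s, the recording span of one tracer video.
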
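"""Gaussian distance decay: deriving the friction coefficient.

The catchment threshold d_max and the weight floor w_min jointly fix the
Gaussian kernel f(d) = exp(-d^2/beta): beta is chosen so that the weight
at the threshold equals the floor.
"""

from fcaccess import DecayParams, derive_beta, gaussian_weight, subzone_scheme

d_max, w_min = 30.0, 0.01
beta = derive_beta(d_max, w_min)
print(f"30-minute catchment, weight floor {w_min} -> beta = {beta:.4f} min^2")
for d in (0, 5, 15, 30):
    print(f"  weight at {d:>2} min: {gaussian_weight(d, beta):.5f}")
# weight halves-of-halves: at 15 min (half the threshold) the weight is
# w_min**0.25 ~ 0.316 -- far higher than the floor, which is the point of
# a Gaussian rather than linear decay.

print("\nDiscrete subzone scheme (4 equal bands over 20 min):")
for lo, hi, rep in subzone_scheme(20.0, 4):
    w = gaussian_weight(rep, derive_beta(20.0, w_min))
    print(f"  [{lo:>4.1f}, {hi:>4.1f}) -> weighted at d={rep} -> {w:.5f}")

params = DecayParams.from_threshold(d_max, w_min)
print(f"\nparams: {params}")
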
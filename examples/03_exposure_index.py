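"""Chemical mixture-exposure index and risk level.

For a multi-substance emission the combined shift-weighted index is the
ratio of summed exposure indices to summed permissible limits (threshold
limit values); the index then maps to a risk level through a two-threshold
ladder (<= 0.5 low, <= 1.0 medium, above high).
"""

from chemrisk import ExposureRecord, mixture_exposure_index, risk_level

mixture = [
    ExposureRecord("acetone", Ps=0.60, NDS=1.00),
    ExposureRecord("toluene", Ps=0.20, NDS=0.50),
    ExposureRecord("ethanol", Ps=0.35, NDS=1.90),
]

idx = mixture_exposure_index(mixture)
print(f"ratio-of-sums mixture index: {idx:.3f} -> risk level {risk_level(idx)!r}")

idx_conv = mixture_exposure_index(mixture, rule="conventional")
print(f"conventional additive index: {idx_conv:.3f} -> risk level {risk_level(idx_conv)!r}")

# The two conventions can disagree near a threshold: the additive rule
# weights each substance by its own limit and is the stricter of the two
# whenever limits differ widely.
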
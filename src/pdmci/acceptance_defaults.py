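"""Documented default planted effects for the synthetic study conditions.

These are the generator-documented effect sizes under which the recovery
properties of the pipeline are stated: an inward mesh-patch displacement
of 1.0 mm (about 3x the 0.3 mm smooth-field SD) on the right hippocampus
of the mixed subtype, a kurtosis-lowering marginal blend of 0.5 on the
right-hippocampus intensities of the mixed subtype, and a 1.5
within-group-SD FA decrease over 15 consecutive segments of the right
inferior fronto-occipital fascicle in the posterior-cortical and mixed
subtypes.
"""

from __future__ import annotations

from .synthetic import EffectSpec


def default_effects() -> list[EffectSpec]:
    return [
        EffectSpec(modality="shape", target="right_hippocampus",
                   affected_groups=("PD-MS",), size=1.0,
                   patch_center=0, patch_size=100),
        EffectSpec(modality="texture", target="right_hippocampus",
                   affected_groups=("PD-MS",), size=0.5,
                   feature="kurtosis"),
        EffectSpec(modality="tract", target="right_ifof",
                   affected_groups=("PD-PC", "PD-MS"), size=1.5,
                   interval=(40, 54)),
    ]
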
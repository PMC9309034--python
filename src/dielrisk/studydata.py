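"""Published field-study estimates used by the derived-statistics layer.

Point estimates from the motivating multi-predator white-tailed deer
study in Michigan's western Upper Peninsula (2009-2019 telemetry, 2017-2019
cameras): temporal overlap (Delta-hat-4) between each mortality source's
activity and deer nursery groups / adult deer, and the cause-specific
cumulative mortality incidence for collared fawns and adults.  These are
*inputs* to the derived-percentage operations (relative overlap changes,
group averages, mortality ratios) — the package does not re-estimate them,
it consumes them the way a reader of the study's summary table would.
"""

#: Delta-hat-4 overlap of each source's diel activity with deer groups.
OVERLAP_NURSERY = {
    "black_bear": 0.65,
    "bobcat": 0.44,
    "coyote": 0.41,
    "wolf": 0.61,
    "human": 0.71,
}
OVERLAP_ADULT = {
    "black_bear": 0.85,
    "bobcat": 0.70,
    "coyote": 0.66,
    "wolf": 0.86,
    "human": 0.51,
}

#: terminal cause-specific cumulative incidence (identified sources only).
FAWN_MORTALITY_RATE = {
    "bear": 0.01,
    "bobcat": 0.02,
    "coyote": 0.04,
    "wolf": 0.01,
    "vehicle": 0.03,
}
ADULT_MORTALITY_RATE = {
    "bear": 0.00,
    "bobcat": 0.00,
    "coyote": 0.005,  # printed as <0.01
    "wolf": 0.01,
    "vehicle": 0.01,
}

#: season-long total mortality (all causes, including unidentified
#: predation and disease).
FAWN_TOTAL_MORTALITY = 0.16
ADULT_TOTAL_MORTALITY = 0.03
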
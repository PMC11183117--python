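"""Versioned base tables for the toy epidemic simulator.

These are the published OpenABM/DeepABM transmission constants: per-age
susceptibility scalars over nine age groups (0-10, 11-20, ..., 71-80, 80+),
per-disease-stage infectiousness scalars over the eleven canonical stages,
network-duration scalars for the three interaction network types, and the
gamma infectivity-profile parameters (mean and variance, in days).
"""

AGE_GROUPS = (
    "0-10", "11-20", "21-30", "31-40", "41-50",
    "51-60", "61-70", "71-80", "80+",
)

#: Susceptibility scalar S_a per age group of the susceptible agent.
AGE_SUSCEPTIBILITY = (0.35, 0.69, 1.03, 1.03, 1.03, 1.03, 1.27, 1.52, 1.52)

#: Canonical disease stages and their infectiousness scalars A_s.
DISEASE_STAGES = (
    "susceptible", "asymptomatic", "presymptomatic_mild",
    "presymptomatic_severe", "mild_symptomatic", "severe_symptomatic",
    "hospitalized", "critical_icu", "death", "hospitalized_recovering",
    "recovered",
)
STAGE_INFECTIOUSNESS = (0.0, 0.33, 0.05, 0.05, 0.72, 1.0,
                        0.0, 0.0, 0.0, 0.0, 0.0)

#: Interaction-duration scalar B_n per network type.
NETWORK_SCALARS = {"household": 2.0, "occupation": 1.0, "random": 0.25}

#: Gamma infectivity profile: mean and variance of days since infection.
GAMMA_MEAN = 5.5
GAMMA_VARIANCE = 2.14
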
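# Allometric coefficients for the bioenergetic consumer-resource model.
#
# Every mass-specific rate scales with body mass as  rate = a * M^exponent
# (M in kg, exponent -0.25 by default).  The coefficients below follow the
# classic bioenergetic parametrization lineage (Yodzis-Innes-style constants
# as normalized in later food-web dynamics studies): producer maximum growth
# is the reference time scale (a_r = 1), respiration coefficients are
# expressed relative to it (0.314 for invertebrates, 0.88 for vertebrate
# ectotherms), and maximum ingestion is respiration times the empirical
# maximum-consumption-to-metabolism ratio (8 for invertebrates, 4 for
# vertebrate ectotherms).  Because the dynamics are integrated in time units
# normalized to the fastest producer's growth rate, only rate ratios matter;
# the absolute scale of a_r cancels.
#
# e: assimilation efficiency (fraction of ingested biomass converted to
#    consumer biomass), by resource type: 0.45 for plant material, 0.85 for
#    animal material — conventional values in this model lineage.
# f_e: ingestion efficiency (fraction of killed biomass actually ingested).
#
# Edit this file (or pass overrides) to change any value; the package never
# invents coefficients silently.
a_r: 1.0
a_J_invertebrate: 2.512
a_J_vertebrate: 3.52
a_T_invertebrate: 0.314
a_T_vertebrate: 0.88
allometric_exponent: -0.25
e_producer_link: 0.45
e_animal_link: 0.85
f_e: 1.0
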
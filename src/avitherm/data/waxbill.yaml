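# Default trait values for the common waxbill (Estrilda astrild) study cohort.
# Keys follow the conventional endotherm-model mnemonics.
AMASS: 7.99            # body mass, g
TC: 39.1               # night core body temperature, degC
TC_DAY: 41.6           # daytime core body temperature, degC
TC_MAX: 44.0           # maximum core body temperature, degC
TB_INCREMENT: 0.25     # body-temperature step under heat stress, degC
SHAPE_B_MAX: 3.0       # max ellipsoid long/short axis ratio
DHAIR: 0.03            # feather fiber diameter, mm
LHAIR_DORSAL: 16.1     # feather length, dorsal, mm
LHAIR_VENTRAL: 14.1    # feather length, ventral, mm
ZFUR_DORSAL: 2.0       # feather coat depth, dorsal, mm
ZFUR_VENTRAL: 2.5      # feather coat depth, ventral, mm
RHO: 50.0              # feather fiber density, 1/mm2
QBASAL: 0.17           # basal (night) metabolic rate, W (autumn mean)
QRESTING: 0.37         # daytime resting metabolic rate, W
BODY_DENSITY: 875.0    # kg/m3
FAT_FRACTION: 0.04     # body fat fraction
FIBER_CONDUCTIVITY: 0.209   # W/mK
O2_EXTRACTION: 0.25    # respiratory O2 extraction efficiency
BREATH_OFFSET: 5.0     # expired air minus ambient temperature, degC
WET_SKIN: 0.01         # wet skin fraction for cutaneous evaporation
PANT_MAX: 15.0         # maximum ventilation multiplier at full panting
PANT_MULTIPLIER: 1.0   # metabolic cost multiplier at maximum panting
DIGESTION_COEFFICIENT: 0.83  # NEI digestion-cost coefficient
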
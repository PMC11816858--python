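"""Calibration anchors: published summary values the generators reproduce.

These constants pin the synthetic-data generators to the measured
experiment: 10B uptake at the 4 h peak, comet %tail-DNA summaries 1 h after
irradiation, spheroid circularity bands, and the per-culture boron
concentrations used for dose planning.  They are versioned data, not tuning
knobs; a test asserts them verbatim.
"""

from types import MappingProxyType

#: ug 10B per 1e6 cells at the 4 h uptake peak: (mean, SD over 3 measurements)
UPTAKE_4H = MappingProxyType({
    "HEMa-LP": (0.238, 0.017),
    "WM266-4-2D": (0.156, 0.002),
    "FM55p-2D": (0.057, 0.015),
    "FM55p-3D": (0.70, 0.15),
    "WM266-4-3D": (0.25, 0.03),
})

#: %tail-DNA 1 h after irradiation for boron-loaded irradiated samples:
#: (cell line / model, dose group) -> (mean, SE)
COMET_1H = MappingProxyType({
    ("FM55p-2D", "lower"): (16.4, 0.5),
    ("HEMa-LP", "lower"): (18.3, 1.1),
    ("FM55p-3D", "lower"): (19.9, 0.8),
    ("FM55p-3D", "higher"): (24.4, 0.6),
    ("WM266-4-3D", "lower"): (14.9, 0.9),
    ("WM266-4-3D", "higher"): (18.7, 0.6),
})

#: Spheroid circularity bands (dimensionless)
CIRCULARITY_CONTROL = (0.81, 0.84)
CIRCULARITY_IRRADIATED = (0.87, 0.90)

#: Boron concentration in cells at irradiation, ppm: (mean, 1-sigma)
C_B_PPM = MappingProxyType({
    "WM266-4-2D": (27.5, 0.5),
    "FM55p-2D": (9.2, 2.0),
    "HEMa-LP": (26.4, 1.7),
    "WM266-4-3D": (36.0, 6.8),
    "FM55p-3D": (47.5, 4.6),
})

PROFILES = tuple(UPTAKE_4H)
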
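{
  "name": "wide-angle schematic eye (unaccommodated Navarro parameter set)",
  "reference": "Escudero-Sanz I. & Navarro R., 'A wide-angle schematic eye model', J. Opt. Soc. Am. A 16(8):1881-1891 (1999)",
  "version": 1,
  "surfaces": [
    {"name": "anterior cornea", "radius_mm": 7.72, "conic": -0.26, "thickness_mm": 0.55, "medium": "cornea", "semi_aperture_mm": 6.0},
    {"name": "posterior cornea", "radius_mm": 6.5, "conic": 0.0, "thickness_mm": 3.05, "medium": "aqueous", "semi_aperture_mm": 6.0},
    {"name": "anterior lens", "radius_mm": 10.2, "conic": -3.1316, "thickness_mm": 4.0, "medium": "lens", "semi_aperture_mm": 5.0},
    {"name": "posterior lens", "radius_mm": -6.0, "conic": -1.0, "thickness_mm": 16.3203, "medium": "vitreous", "semi_aperture_mm": 5.0}
  ],
  "retina": {"radius_mm": -12.0, "conic": 0.0, "semi_aperture_mm": 11.5},
  "dispersion": {
    "wavelengths_nm": [458.0, 543.0, 589.3, 632.8],
    "cornea": [1.3828, 1.3777, 1.376, 1.3747],
    "aqueous": [1.3445, 1.3391, 1.3374, 1.336],
    "lens": [1.4292, 1.4222, 1.42, 1.4183],
    "vitreous": [1.3428, 1.3377, 1.336, 1.3347]
  }
}
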
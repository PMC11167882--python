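"""Moles of each gas component in a serum-bottle headspace.

Converts a manometer gauge reading plus gas-chromatograph component
fractions into millimoles via the ideal gas law (absolute pressure = gauge +
1013.25 mbar; R = 83.140 mbar.L/(mol.K); 75 mL headspace at 38 degC).
"""

from carboxkin import BatchBottleConfig, GasReading, gas_moles

bottle = BatchBottleConfig()  # headspace 0.075 L, 311.15 K

gauge_mbar = 450.0  # overpressure just before depressurization
composition = {"CO2": 62.0, "H2": 9.5, "CH4": 0.4, "N2": 28.1}

print(f"gauge {gauge_mbar:.0f} mbar -> absolute "
      f"{gauge_mbar + 1013.25:.2f} mbar, headspace {bottle.headspace_volume} L")
total = 0.0
for component, pct in composition.items():
    reading = GasReading(gauge_mbar, pct, bottle.temperature, component)
    mmol = gas_moles(reading, bottle.headspace_volume)
    total += mmol
    print(f"  {component:<4} {pct:>5.1f} %  ->  {mmol:.3f} mmol")
print(f"  total        ->  {total:.3f} mmol"
      "\n\nCO2 and H2 are the fermentation gases of interest; their mmol"
      "\ncounts accumulate over the daily depressurization events.")
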
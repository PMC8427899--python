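# Biodiesel standard limits for FAME-predicted fuel properties.
# Property keys match FuelPropertyReport field names; a property missing
# from a standard is not specified by it.
#
# version 1: ASTM D6751 (USA), EN 14214 (Europe), IS 15607 (India).
# Saponification value is left unspecified in all three standards: none of
# them regulates SV directly (limits occasionally quoted for it refer to
# other assays).
# Cloud/pour point are climate-dependent guidance values; the ASTM ranges
# below are the commonly used continental-climate windows.
version: 1
standards:
  ASTM D6751:
    kv: {min: 1.9, max: 6.0}
    density: {min: 0.86, max: 0.90}
    cp: {min: -15.0, max: -5.0}
    pp: {min: -20.0, max: -6.0}
    os: {min: 3.0}
    cn: {min: 47.0}
  EN 14214:
    kv: {min: 3.5, max: 5.0}
    density: {min: 0.86, max: 0.90}
    iv: {max: 120.0}
    os: {min: 6.0}
    cn: {min: 51.0}
    c18_3_percent: {max: 12.0}
    fame_ge4_db_percent: {max: 1.0}
  IS 15607:
    kv: {min: 2.5, max: 6.0}
    density: {min: 0.86, max: 0.90}
    cn: {min: 51.0}
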
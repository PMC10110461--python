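{
  "k_on_peak": 120.0,
  "k_off_peak": 8.0,
  "k_exc_peak": 490.0,
  "brightness": 0.02,
  "dipole_angle_abs_em": 0.0,
  "intermediate_rate": null,
  "bleach_rate": 0.0,
  "provenance": {
    "status": "order-of-magnitude defaults",
    "note": "Peak rates per W/cm^2 estimated from typical rsEGFP2 absorption cross-sections and switching quantum yields; not calibrated against any single instrument. Enable the dark shelving intermediate (intermediate_rate = 4e4 /s, slow fluorescence tail ~50 us) to emulate the multi-exponential OFF-switching seen at high 488-nm power.",
    "units": {"k_on_peak": "1/s per W/cm^2 at 405 nm", "k_off_peak": "1/s per W/cm^2 at 488 nm", "k_exc_peak": "1/s per W/cm^2 at 488 nm", "brightness": "detected photons per excitation"}
  }
}
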
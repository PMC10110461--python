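{
  "k_on_peak": 90.0,
  "k_off_peak": 30.0,
  "k_exc_peak": 420.0,
  "brightness": 0.015,
  "dipole_angle_abs_em": 0.0,
  "intermediate_rate": null,
  "bleach_rate": 0.0,
  "provenance": {
    "status": "order-of-magnitude placeholders",
    "note": "Dronpa M159T is a fast OFF-switching variant; rates are plausible magnitudes relative to rsEGFP2, not measurements.",
    "units": {"k_on_peak": "1/s per W/cm^2 at 405 nm", "k_off_peak": "1/s per W/cm^2 at 488 nm", "k_exc_peak": "1/s per W/cm^2 at 488 nm", "brightness": "detected photons per excitation"}
  }
}
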
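{
  "schema_version": 1,
  "comment": "Published 91-day event counts from the 34-room high-risk monitor sample, used as report inputs.",
  "window_days": 91,
  "denominators": {"BP": 47016, "SpO2": 97558, "HR": 143799},
  "mewc": {
    "mewc_sbp_low": 1170,
    "mewc_sbp_high": 910,
    "mewc_dbp_high": 1317,
    "mewc_spo2_low": 4996,
    "mewc_hr_low": 602,
    "mewc_hr_high": 4676
  },
  "flashing": {
    "flash_sbp_low": 581,
    "flash_sbp_high": 1021,
    "flash_dbp_high": 483,
    "flash_hr_high": 2168
  },
  "ob_pages": {
    "flash_sbp_low": 87,
    "flash_sbp_high": 260,
    "flash_dbp_high": 37,
    "flash_hr_high": 190
  },
  "unit_pages_to_ob": 947,
  "unit_nurse_pages": 1180
}
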
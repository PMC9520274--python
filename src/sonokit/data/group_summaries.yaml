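# Published per-group summary statistics (mean, sd in %) for the
# sonoporation experiments this package models: fluorescent-cell fractions
# per delivered molecule and viability relative to sham. These are summary
# values only; replicate-level draws generated from them are synthetic.
#
# Group naming: tmb_us_<n> = targeted microbubbles + ultrasound at <n> kPa
# peak negative pressure; us_only / tmb_only are the single-arm controls.

- molecule: 7aad_1.2kDa
  metric: count_fraction
  timepoint_h: 0
  groups:
    sham:        {mean: 21.0,  sd: 3.0}
    us_only:     {mean: 24.0,  sd: 3.3}
    tmb_us_100:  {mean: 21.5,  sd: 0.9}
    tmb_us_500:  {mean: 57.7,  sd: 4.9}
    tmb_us_800:  {mean: 52.0,  sd: 6.3}

- molecule: fitc_4kDa
  metric: area_fraction
  timepoint_h: 24
  groups:
    sham:        {mean: 0.77,  sd: 0.21}
    us_only:     {mean: 0.22,  sd: 0.12}
    tmb_only:    {mean: 2.05,  sd: 0.86}
    tmb_us_500:  {mean: 29.39, sd: 5.07}
    tmb_us_800:  {mean: 24.14, sd: 4.46}

- molecule: fitc_20kDa
  metric: area_fraction
  timepoint_h: 24
  groups:
    sham:        {mean: 0.76,  sd: 0.41}
    tmb_us_100:  {mean: 4.34,  sd: 1.86}
    tmb_us_200:  {mean: 5.57,  sd: 3.01}
    tmb_us_300:  {mean: 8.14,  sd: 1.95}
    tmb_us_500:  {mean: 10.34, sd: 1.03}
    tmb_us_800:  {mean: 13.23, sd: 1.32}

- molecule: fitc_70kDa
  metric: area_fraction
  timepoint_h: 24
  groups:
    sham:        {mean: 0.24,  sd: 0.03}
    tmb_us_100:  {mean: 1.4,   sd: 0.12}
    tmb_us_200:  {mean: 4.22,  sd: 0.52}
    tmb_us_300:  {mean: 4.33,  sd: 1.19}
    tmb_us_500:  {mean: 5.3,   sd: 1.4}
    tmb_us_800:  {mean: 4.32,  sd: 0.6}

- molecule: fitc_4kDa
  metric: viability_percent
  timepoint_h: 24
  groups:
    sham:        {mean: 100.0, sd: 9.04}
    us_only:     {mean: 93.19, sd: 11.9}
    tmb_only:    {mean: 22.87, sd: 1.01}
    tmb_us_100:  {mean: 22.57, sd: 3.9}
    tmb_us_500:  {mean: 12.1,  sd: 0.92}
    tmb_us_800:  {mean: 7.92,  sd: 0.42}

- molecule: fitc_4kDa
  metric: viability_percent
  timepoint_h: 72
  groups:
    # sham is definitionally 100% (viability is normalized to it)
    sham:        {mean: 100.0, sd: 0.0}
    tmb_only:    {mean: 85.83, sd: 2.17}
    tmb_us_100:  {mean: 85.73, sd: 1.67}
    tmb_us_500:  {mean: 52.84, sd: 10.5}
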
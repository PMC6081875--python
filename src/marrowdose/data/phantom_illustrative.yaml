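# Illustrative synthetic reference-phantom configuration for tests and examples.
#
# These are NOT tabulated Monte-Carlo S values: magnitudes are plausible for
# Lu-177 organ-level dosimetry but the numbers are synthetic.  Replace this
# file with your institution's phantom tabulation for any real calculation.
#
# Masses in kg, S values in Gy/(Bq h).  Exponents a, b, c are the non-linear
# mass-scaling defaults per sex and may be omitted (they then default).
male:
  sex: male
  m_wb_kg: 73.7
  m_bm_kg: 1.17
  m_organ_kg:
    kidneys: 0.310
    liver: 1.81
    spleen: 0.183
  s_bm_bm: 7.6e-11
  s_bm_wb: 4.3e-12
  s_bm_organ:
    kidneys: 2.0e-12
    liver: 8.0e-13
    spleen: 1.5e-12
female:
  sex: female
  m_wb_kg: 56.9
  m_bm_kg: 0.90
  m_organ_kg:
    kidneys: 0.275
    liver: 1.40
    spleen: 0.150
  s_bm_bm: 9.9e-11
  s_bm_wb: 5.6e-12
  s_bm_organ:
    kidneys: 2.6e-12
    liver: 1.0e-12
    spleen: 1.9e-12
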
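# Default mountain altitudinal belt (MAB) table: Taibai Mountain.
# Within each slope the belts must be contiguous and non-overlapping;
# intervals are half-open [alt_lo, alt_hi) except the summit belt,
# which is closed at the top so the peak is covered.
name: taibai
basal_formation: Basal zone
slopes:
  north:
    - {formation: Basal zone, alt_lo: 0, alt_hi: 800}
    - {formation: Quercus variabilis forest, alt_lo: 800, alt_hi: 1000}
    - {formation: Quercus aliena var. acuteserrata forest, alt_lo: 1000, alt_hi: 1900}
    - {formation: Quercus liaotungensis forest, alt_lo: 1900, alt_hi: 2300}
    - {formation: mixed forests of Betula albosinensis with Pinus armandii, alt_lo: 2300, alt_hi: 2700}
    - {formation: Betula albosinensis var. septentrionalis forest, alt_lo: 2700, alt_hi: 2800}
    - {formation: Abies fargesii forest, alt_lo: 2800, alt_hi: 3000}
    - {formation: Larix chinensis forest, alt_lo: 3000, alt_hi: 3400}
    - {formation: subalpine shrub and meadow, alt_lo: 3400, alt_hi: 3777}
  south:
    - {formation: Basal zone, alt_lo: 0, alt_hi: 750}
    - {formation: Quercus variabilis forest, alt_lo: 750, alt_hi: 1300}
    - {formation: Quercus aliena var. acuteserrata forest, alt_lo: 1300, alt_hi: 2000}
    - {formation: mixed forests of Betula albosinensis with Pinus armandii, alt_lo: 2000, alt_hi: 2300}
    - {formation: mixed forests of Betula albosinensis with Betula albosinensis var. septentrionalis, alt_lo: 2300, alt_hi: 2650}
    - {formation: Abies fargesii forest, alt_lo: 2650, alt_hi: 3000}
    - {formation: Larix chinensis forest, alt_lo: 3000, alt_hi: 3400}
    - {formation: subalpine shrub and meadow, alt_lo: 3400, alt_hi: 3777}
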
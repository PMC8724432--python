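# Molar extinction coefficients of hemoglobin species, compiled literature
# values (cm^-1 per mol/L); converted internally to mm^-1 per uM via
# ln(10) * 1e-7.  Table is configuration: edit or replace to change the
# chromophore model.
chromophore,wavelength_nm,epsilon_molar_cm_inv_M
Hb,660,3226.56
HbO2,660,319.60
Hb,750,1405.24
HbO2,750,518.00
Hb,840,693.04
HbO2,840,1022.00
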
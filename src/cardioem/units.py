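"""Unit conventions used throughout the package.

The mechanical core works in a consistent (mm, ms, mg, kPa) system:

=============  =======================  =====================================
quantity       unit                     notes
=============  =======================  =====================================
length         mm
time           ms
mass           mg                       1 mg = 1e-6 kg
stress         kPa                      1 kPa = 1 mg / (mm * ms^2)
force          kPa*mm^2 = mN * 1e-3     "milli-Newton * 1e-3" = microNewton*?
density        mg/mm^3                  water = 1.0
pressure       kPa internally;          mmHg at circulation interfaces
voltage        mV
conductivity   mS/mm                    1 S/m = 1e-3 S/mm = 1 mS/mm
volume         mm^3 internally;         mL = 1000 mm^3 at reporting surfaces
=============  =======================  =====================================

With these units Rayleigh damping coefficients convert as
alpha_R = 100 1/s = 0.1 1/ms and beta_R = 0.04 s = 40 ms.
"""

#: kPa per mmHg
KPA_PER_MMHG = 0.1333223684
#: mmHg per kPa
MMHG_PER_KPA = 1.0 / KPA_PER_MMHG
#: mm^3 per mL
MM3_PER_ML = 1000.0
#: myocardial density, mg/mm^3 (1.053 g/cm^3)
RHO_MYOCARDIUM = 1.053


def mmhg_to_kpa(p):
    return p * KPA_PER_MMHG


def kpa_to_mmhg(p):
    return p * MMHG_PER_KPA


def mm3_to_ml(v):
    return v / MM3_PER_ML


def ml_to_mm3(v):
    return v * MM3_PER_ML
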
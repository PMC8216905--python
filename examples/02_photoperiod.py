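"""Compute the three light regimes: darkness, central and northern Europe.

Sunrise/sunset come from the NOAA solar geometry; lamps ramp linearly for
one hour before being fully on (dawn) and fully off (dusk).
"""

import datetime as dt

from phenobee.scenario import build_photoperiod_schedule, day_length
from phenobee.solar import SNASA, WURZBURG

span = (dt.date(2017, 11, 14), dt.date(2018, 4, 16))
cd = build_photoperiod_schedule("CD", None, span)
cep = build_photoperiod_schedule("CEP", WURZBURG, span)
nep = build_photoperiod_schedule("NEP", SNASA, span)

for d in (dt.date(2017, 12, 21), dt.date(2018, 2, 15), dt.date(2018, 4, 1)):
    print(f"{d}: CD {day_length(cd, d):4.1f} h, "
          f"CEP (Wuerzburg) {day_length(cep, d):5.2f} h, "
          f"NEP (Snåsa) {day_length(nep, d):5.2f} h")

st = cep.sun_times(dt.date(2018, 2, 15))
half = st.sunrise - dt.timedelta(minutes=30)
print(f"\n2018-02-15 Wuerzburg sunrise {st.sunrise.strftime('%H:%M')} CET; "
      f"lamp fraction 30 min earlier = {cep.light_fraction(half):.2f} "
      "(mid-ramp of the 1-h dawn)")
print("The northern photoperiod is shorter all winter and overtakes the "
      "central one after the March equinox.")
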
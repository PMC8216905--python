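"""Independent solar oracle shared by tests: Spencer (1971) Fourier series."""

import datetime as dt
import math


def spencer_day_length_h(lat_deg: float, date: dt.date) -> float:
    doy = date.timetuple().tm_yday
    g = 2.0 * math.pi / 365.0 * (doy - 1 + 0.5)
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    lat = math.radians(lat_deg)
    cos_ha = (
        math.cos(math.radians(90.833)) / (math.cos(lat) * math.cos(decl))
        - math.tan(lat) * math.tan(decl)
    )
    cos_ha = min(1.0, max(-1.0, cos_ha))
    return 2.0 * math.degrees(math.acos(cos_ha)) / 15.0
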
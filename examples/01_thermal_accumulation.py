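"""Chill-unit and growing-degree-hour accumulation over a synthetic winter.

Generates an hourly cold-year temperature record, accumulates Utah chill
units from the start of autumn and GDH over the same window, and prints the
season totals plus the date 1000 CU is first reached (a typical sweet
cherry chilling requirement).
"""

import numpy as np

from cherrychill import SeasonSpec, accumulate, gen_temperature_series

series = gen_temperature_series(SeasonSpec(year_type="cold", seed=1))
window = (series.season_start, series.times[-1])
chill = accumulate(series, window, "chill")
heat = accumulate(series, window, "heat")

reached = np.nonzero(chill.cumulative >= 1000.0)[0]
print(f"season: {series.times[0].date()} .. {series.times[-1].date()}")
print(f"total chill units (Utah):   {chill.total:8.1f} CU")
print(f"total growing degree hours: {heat.total:8.1f} GDH")
print(f"1000 CU first reached:      {chill.times[reached[0]]}")
# The CU total is the winter's chilling supply; the crossing date is when a
# cultivar needing 1000 CU would satisfy its chilling requirement.
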
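"""Dating the break of endodormancy from weekly forcing tests.

Simulates a winter with a planted 1000 CU chilling requirement and weekly
forcing tests, classifies each test by the 30% weight-gain criterion, and
converts the first broken date into the recovered chilling requirement.
"""

from cherrychill import SeasonSpec, chilling_requirement, estimate_break_date
from cherrychill.synthetic import gen_forcing_tests, gen_temperature_series

spec = SeasonSpec(year_type="cold", seed=1, planted_cu_requirement=1000.0)
series = gen_temperature_series(spec)
tests = gen_forcing_tests(series, spec, cadence_days=7)

det = estimate_break_date(tests, threshold_pct=30.0)
for date, ratio in det.ratio_series:
    flag = " <- break" if det.break_date is not None and date == det.break_date else ""
    print(f"{date.date()}  forced/field ratio {ratio:5.3f}{flag}")

cu, _ = chilling_requirement(series, det)
print(f"\nplanted requirement : 1000.0 CU")
print(f"recovered requirement: {cu:6.1f} CU (CU accumulated before the break date)")
# The first date whose forced buds outweigh field buds by >= 30% dates the
# release of endodormancy; chill accumulated to that date estimates the
# cultivar's chilling requirement.
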
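"""Carbon-stock accounting: 5-year span means, increments, cumulative
increments and CO2 equivalents from an annual national stock series.

The stock series here is a simple constructed example (Pg C per year);
in the pipeline it comes from area-integrating predicted density grids.
"""
import numpy as np
import pandas as pd

from forestcarbon import co2_equivalent, span_table

# eight 5-year spans of national stock (Pg C)
span_means = [32.89, 32.84, 32.87, 32.95, 33.16, 33.76, 33.67, 34.21]
series = pd.Series(np.repeat(span_means, 5), index=np.arange(1982, 2022))

tbl = span_table(series, span=5, baseline="first-span")
print(tbl.round(3).to_string(index=False))
final = tbl.iloc[-1]
print(f"\n40-year cumulative gain: {final.cumulative_increment_pgc:.2f} Pg C "
      f"= {final.cumulative_co2_bt:.2f} Bt CO2 absorbed from the atmosphere")
print(f"(conversion: 1 Pg C -> {co2_equivalent(1.0):.2f} Bt CO2; "
      "increments always telescope to the final cumulative value)")
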
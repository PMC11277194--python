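"""Simulate a 78-year climate/outbreak record and inspect its structure.

The generator plants the documented relationship for wheat blossom
midge: severity falls with warm January-March weather and rises with
wet July-September weather in the previous year.  The printed
correlations should be clearly negative and positive respectively.
"""

import numpy as np

from gepcast import generate_synthetic

df = generate_synthetic(n_years=78, seed=0, start_year=1933)

winter_temp = df[["temp_jan", "temp_feb", "temp_mar"]].mean(axis=1)
prev_rain = df[["rain_jul", "rain_aug", "rain_sep"]].mean(axis=1).shift(1)
level = df["level"].astype(float)
mask = prev_rain.notna()

print(df.head().to_string(index=False))
print()
print(f"level frequencies           : {df['level'].value_counts().sort_index().to_dict()}")
print(f"corr(level, winter temp)    : {np.corrcoef(winter_temp, level)[0, 1]:+.3f}")
print(f"corr(level, prev summer rain): "
      f"{np.corrcoef(prev_rain[mask], level[mask])[0, 1]:+.3f}")
print()
print("Negative winter-temperature and positive prior-rain correlations")
print("are the planted climate drivers the forecaster has to learn.")
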
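"""Changes over time between the two survey waves.

Reports raw and annualised, absolute and relative changes for the headline
measures with delta-method uncertainty, using the reference-year rule for
the multi-year second survey ("2014-2016" -> 2015).
"""

from common import pipeline_config
from mpikit import run_pipeline
from mpikit.cot import reference_year

result = run_pipeline(pipeline_config())
cf = result.change_file

nat = cf[(cf["loa"] == "nat") & cf["measure"].isin(["H", "M0"])]
print("national changes 2010 -> 2014-2016 "
      f"(dt = {reference_year('2014-2016') - reference_year('2010'):.1f} years):")
cols = ["measure", "ctype", "ann", "b", "se", "tval"]
print(nat[cols].round(4).to_string(index=False))

sig = nat[(nat["ann"] == 1) & nat["tval"].abs().gt(1.96)]
print(f"\n{len(sig)} of {len(nat[nat['ann'] == 1])} annualised national "
      "changes are significant at the 5% level")
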
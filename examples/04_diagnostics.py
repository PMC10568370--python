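"""Pre-flight diagnostics: elemental balances, FVA ranges, attainable growth.

Before adjusting anything, check *why* a measured scenario fails: here the
glucose uptake is underreported at half its true value, so the measured
products plus biomass demand more carbon than the measured substrate
supplies — a gross imbalance no flux distribution can fix, visible as a
negative carbon net.
"""

from fbarebalance import (
    Measurement,
    MeasurementSet,
    ToyModelParams,
    elemental_balance,
    fva_precheck,
    make_toy_model,
    max_growth,
    simulate_measurements,
)

model = make_toy_model(ToyModelParams(seed=0))
good = simulate_measurements(model)

entries = {k: m for k, m in good}
glc = entries["EX_glc__D"]
entries["EX_glc__D"] = Measurement(glc.value * 0.5, sd=0.1)
bad = MeasurementSet(entries)

report = elemental_balance(model, bad)
print("elemental balance over the measured rates [mmol/(gDW*h)]:")
for element in sorted(report.net):
    print(f"  {element}: {report.net[element]:+.3f}")

ranges = fva_precheck(model, bad)
print("\nFVA ranges (model constraints only):")
for rxn_id, rng in ranges.items():
    flag = "ok" if rng.in_range else "OUT OF RANGE"
    print(f"  {rxn_id}: {rng.measured:.3f} in [{rng.minimum:.3f}, "
          f"{rng.maximum:.3f}]  {flag}")

mu_max = max_growth(model, {"EX_glc__D": entries["EX_glc__D"].value})
print(f"\nmax attainable growth at the reported uptake: {mu_max:.4f} 1/h "
      f"(measured growth: {bad['BIOMASS'].value:.4f} 1/h)")
print(
    "\nThe negative carbon net and the unreachable growth rate both point "
    "at the uptake measurement, not at the biomass composition."
)
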
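# seastress

Diagnostics for ocean warming and acidification extreme days under
contrasting threshold definitions, plus a synthetic multi-scenario
generator standing in for daily Earth-system-model output.

## The problem

Counting "extreme days" in an ocean projection — marine heatwave days,
acidification extremes, coral thermal stress — depends critically on how
the threshold is defined:

- **Seasonally constant (SC)** thresholds take one percentile (95th for
  SST, H+ and pCO2; 5th for aragonite saturation Ωa) of all days in a
  reference period, so extremes cluster in the warm season.
- **Seasonally varying (SV)** thresholds add a percentile anomaly to the
  mean seasonal cycle, so extremes can occur year-round.
- **Fixed baselines** use a static reference period (1975–2014); an
  organism experiencing them would see permanent extreme conditions by
  late century under any scenario.
- **Adaptive baselines** recompute the threshold from a rolling window of
  the preceding 100 years, representing gradual adaptation; under them,
  the benefit of emissions mitigation becomes visible again.

The package implements all four combinations for four surface-ocean
variables (SST, hydrogen-ion concentration, pCO2, Ωa), plus degree heating
weeks (DHW) for coral thermal stress, absolute physiological thresholds
(Ωa < 1, Ωa < 3, pCO2 > 1000 μatm), compound (multi-stressor) events,
detrended percentile-change statistics, and site-level reports. A
deterministic synthetic generator produces daily and monthly fields for
three scenarios (`historical`, `mitigation`, `high`) that share one noise
realization and diverge after 2040. See `docs/methods.md` for the model
and numerical details.

## Worked example

Extreme-day percentages (area-weighted global means) under fixed vs
adaptive seasonally varying thresholds, on the default synthetic world
with seed 1. Historical counts use 1975–2014; the scenarios use
2061–2100:

```python
import numpy as np
from seastress import gridio, synthetic, thresholds

cfg = synthetic.default_config(seed=1)
scenarios = {s: synthetic.generate_scenario(cfg, s)
             for s in ("historical", "mitigation", "high")}

hist_years, fut_years = (1975, 2014), (2061, 2100)

def percent(mask):
    return float(gridio.global_mean(mask["percent"]))

for var in ("sst", "omega"):
    sv = thresholds.fit_fixed_sv_anomaly(
        scenarios["historical"][var]["daily"], hist_years)
    fixed, adaptive = {}, {}
    for scen, out in scenarios.items():
        years = hist_years if scen == "historical" else fut_years
        daily = out[var]["daily"]
        fixed[scen] = percent(thresholds.count_extremes(daily, sv))
        thr = thresholds.adaptive_sv_thresholds(
            sv, out[var]["monthly"], hist_years,
            np.arange(years[0], years[1] + 1), n_years=100)
        adaptive[scen] = percent(thresholds.count_extremes(daily, thr))
    for name, d in (("fixed SV", fixed), ("adaptive SV", adaptive)):
        print(f"{var:6s} {name:12s} hist {d['historical']:5.1f}%  "
              f"mit {d['mitigation']:5.1f}%  high {d['high']:5.1f}%")
```

Output:

```
sst    fixed SV     hist   5.0%  mit  76.0%  high  96.7%
sst    adaptive SV  hist  31.8%  mit  31.6%  high  82.3%
omega  fixed SV     hist   5.0%  mit 100.0%  high 100.0%
omega  adaptive SV  hist  92.3%  mit  72.7%  high 100.0%
```

Two things to read off. Under the fixed baseline, Ωa saturates at 100%
extreme days under *both* future scenarios — mitigation looks pointless.
Under the adaptive baseline, the mitigation value is closer to the
historical value than to the high-emission value, for every variable (the
Ωa historical value is high because the synthetic Ωa trend is strong even
before 2014 relative to its rolling 100-year envelope).

The same analysis, end to end with files in between, via the CLI:

```sh
seastress init-config --out config.yml --seed 1
seastress run --config config.yml --out runs/demo
# or stage by stage: simulate, thresholds, count, coral, events, report
```

which writes netCDF fields and masks plus `counts/global_means.csv`,
`coral/summary.csv`, `events/change_summary.csv`,
`report/site_report.csv` and a `manifest.json` recording the config hash
and seed. Re-running with the same config and seed reproduces
bit-identical masks.

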
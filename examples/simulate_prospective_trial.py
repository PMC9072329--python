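"""End-to-end simulated prospective validation of an abstaining device.

Emulates the full study design: (1) develop the device on a training
cohort with clean labels — fit one gradient-boosted score model per age
band and calibrate the abstention band on pooled out-of-fold scores
against the PPV >= 0.65 / NPV >= 0.85 floors; (2) freeze the device;
(3) generate an independent 425-child trial cohort, adjudicate each
child through the consensus specialist panel, and score the frozen
device against the panel's reference labels.
"""

from abstaindx import RunConfig, run
from abstaindx.stats import table3_markdown

result = run(RunConfig(mode="simulate_full", seed=1), "scratch/example_run")

print(table3_markdown(result.confusion))
print(f"\ncalibrated band: t_neg={result.thresholds.t_neg:.3f}, "
      f"t_pos={result.thresholds.t_pos:.3f}")
for name, d in result.report.to_dict().items():
    if isinstance(d, dict) and not d["undefined_flag"]:
        print(f"{name:28s} {d['point'] * 100:5.1f}%  ({d['num']}/{d['den']})")

print("\nThe band was calibrated to sit exactly at the floors on clean "
      "training labels, so coverage is high but there is no margin: the "
      "~12% reference-label noise implied by the panel's published "
      "agreement marginals then pulls the observed PPV/NPV below the "
      "floors. The real device maintained its floors prospectively by "
      "abstaining far more (68% vs our simulated indeterminate rate), "
      "trading coverage for robustness.")
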
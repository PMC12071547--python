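"""One call from simulation to the full report, with figures.

Runs simulate -> analyze -> report with the default configuration and
lists the artifacts: metric tables, the group comparison, the threshold
sweep, the JSON summary, and the boxplot/scatter figures.
"""

from pathlib import Path

from anometry import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    simulation=SimulationConfig(seed=1),
    output_dir="scratch/example_report",
    make_figures=True,
)
report = run_pipeline(config)

acc = report["accuracy"]
best = report["threshold_sweep"]["best_youden"]
print(f"{report['n_patients']} patients analysed")
print(f"configured rule: sensitivity {acc['sensitivity']:.2f}, specificity {acc['specificity']:.2f}")
print(
    f"best Youden point on the sweep grid: anterior < {best['anterior_threshold']:.0f} mmHg, "
    f"ratio < {best['ratio_threshold']:.1f} "
    f"(sens {best['sensitivity']:.2f}, spec {best['specificity']:.2f})"
)
print("\nartifacts:")
for path in sorted(Path(config.output_dir).rglob("*")):
    if path.is_file():
        print(f"  {path}")
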
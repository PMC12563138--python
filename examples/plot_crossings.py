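"""Draw the crossing-line figure for each material in the bundled dataset.

Each figure shows the ascending new-bone line, the descending residual-graft
line, the observed points, and a star at the break-even point when one can
be reported; extrapolated segments continue as dashed lines.  Figures are
written to ``crossing_figures/`` next to the current working directory.
"""

from pathlib import Path

from breakeven import analyze_series, load_rabbit_sinus_lift, plot_crossing

outdir = Path("crossing_figures")
outdir.mkdir(exist_ok=True)

for series in load_rabbit_sinus_lift().to_series():
    result = analyze_series(series)
    slug = f"{series.study_label}_{series.material}".lower().replace(" ", "_")
    target = outdir / f"{slug}.png"
    plot_crossing(series, result, target)
    coords = (
        f"{result.time_days:.1f} d / {result.level_pct:.1f}%"
        if result.status.convergent
        else "NA"
    )
    print(f"{target}  ->  {result.status.value:16s} {coords}")
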
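# westgardqc

Statistical process control for clinical-laboratory internal QC at
**control-lot changeover**: derive Levey-Jennings control limits from two
assay-control lots under two competing schemes, evaluate the classic
Westgard multirules, and compare warning/rejection failure counts between
the schemes.

## The problem

A laboratory monitors each assay with stabilized control materials plotted
on a Levey-Jennings chart: sequential control values x_i against horizontal
lines at m ± k·s for k = 1, 2, 3. When a control lot is replaced, the new
lot's own mean and SD are not yet known (convention: establish them over
~20 runs), so laboratories bridge the gap with a **cross-over CV**: the CVs
of the outgoing lot (a) and incoming lot (b) are pooled,

    CV_pooled = sqrt( ((n_a−1)·CV_a² + (n_b−1)·CV_b²) / (n_a + n_b − 2) ),

and converted to a provisional applied SD, s = CV_pooled·|m|/100, around a
target mean m (by default the incoming lot's provisional mean). Once the
incoming lot's **actual** mean x̄ and sample SD s (n−1 denominator) are
established, the limits become x̄ ± k·s.

The Westgard multirules are then evaluated on the standardised series
z_i = (x_i − m)/s:

| rule | fires when | severity |
|------|------------|----------|
| 1_2s | one point with \|z\| > 2 | warning |
| 1_3s | one point with \|z\| > 3 | rejection |
| 2_2s | two consecutive same-side points with \|z\| > 2 | rejection |
| R_4s | consecutive points jumping from > +2 to < −2 (or back) | rejection |
| 4_1s | four consecutive same-side points with \|z\| > 1 | rejection |
| 10_x | ten consecutive points strictly on one side of the mean | rejection |

Because every threshold rule compares z to a fixed cut-off, an applied SD
that overstates the lot's true imprecision (as a pooled transitional SD
can) shrinks every z and monotonically suppresses warning and rejection
failures — real analytical errors are missed. This package quantifies that
mechanism: it re-creates the published 18-chart before/after comparison
(26/21/5 total/warning/rejection failures under cross-over limits versus
36/12/24 under actual limits), and, since the underlying raw measurements
were never published, ships a seeded two-lot Gaussian simulator so every
pipeline stage is testable end to end.

## Worked example

Reproduce the reference 18-group aggregation and its significance tests:

```bash
$ westgard-qc table1 --out-dir out/
before totals: total=26 warning=21 rejection=5
after  totals: total=36 warning=12 rejection=24
```

`out/association.json` then contains (abridged):

```json
{"test_name": "chi_square", "statistic": 11.806, "p_value": 0.00059,
 "significant": true, "odds_ratio": 8.4}
```

Reading: establishing the incoming lot's actual mean/SD raised the total
failure count from 26 to 36 but flipped its composition — rejections rose
from 5 to 24 while warnings fell from 21 to 12. The odds of a failure
being a rejection rather than a warning are 8.4× higher under actual
limits, and the 2×2 chi-square on that composition is significant at
α = 0.05 (p ≈ 0.0006). The paired t-test on per-chart totals is not
(p ≈ 0.37): the schemes disagree on *what kind* of failure is flagged more
than on *how many*.

A full simulated study from the library:

```python
import westgardqc as wq

study = wq.simulate_study(wq.paperlike_configs(seed=1))   # 18 two-lot charts
table = wq.run_comparison(
    study.charts, config=wq.ComparisonConfig(crossover_inflation=1.5)
)
print(table.totals_before)   # cross-over scheme, 1.5x-inflated SD
print(table.totals_after)    # actual per-lot mean/SD
```

or from the shell: `westgard-qc simulate --seed 1 --out-dir sim/`, then
`westgard-qc evaluate sim/controls.csv --scheme crossover|actual` (writes
failure counts, rule hits and annotated Levey-Jennings plots) and
`westgard-qc compare <before> <after>`.

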
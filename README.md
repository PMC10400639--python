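# ecm-comm

Cells embedded in fibrous gels (collagen, fibrin) contract and remodel the
matrix around them; that remodeling propagates tens of cell diameters and can
mechanically couple neighboring cells — *cell-ECM-cell communication*.
Classically this coupling is read off from the visible "band" of dense,
aligned fibers that forms between a pair.  `ecm-comm` implements a more
sensitive, band-independent readout: it correlates the **temporal
fluctuations** of local ECM density adjacent to each cell, after detrending,
and asks whether a pair's fluctuations carry a signature unique to the pair.

The package is aimed at computational biologists and biophysicists who want
to (a) simulate contractile cells in nonlinear fiber networks, (b) quantify
windowed ECM density over time in simulations or 3D confocal-style stacks,
and (c) run the correlation-based communication analyses.

## The measurement

For a cell with density series `x(t)` (z-scored against the onset background,
`z = (ρ − μ_bg)/σ_bg`), fluctuations are the first or second temporal
difference `Δx` or `Δ²x` (chosen by KPSS/ADF stationarity testing), and all
statements are made through Pearson correlations `r(Δ²x_A, Δ²x_B)`:

* **same-versus-different** — fraction of ordered triplets in which a
  communicating pair's correlation exceeds the correlation of one of its
  cells with a cell from a *different* communicating pair;
* **real-versus-fake** — the same comparison against a cell-free matrix
  location at matched distance (controls for locally shared remodeling);
* **matchmaking** — the probability that the true partner ranks first among
  50 candidate partners by correlation (random baseline 1/50 = 0.02);
* **leader–follower** — lagged cross-correlation; the argmax lag orders the
  pair in time.

The simulator represents fibers as trusses that buckle under >2% compression
(tenfold softer) and stiffen exponentially under >2% tension, cells as
circular voids whose boundaries contract radially in 50 steps drawn from
N(μ=1%, σ) of the initial radius, and solves quasi-static equilibrium by
energy minimization after each step.  See `docs/methods.md` for the model,
the quantification windows, and all numerical choices.

## Worked example

Simulate six communicating pairs at pair distance 4 cell diameters
(each pair in its own network), quantify boundary windows, and run the
analyses:

```bash
ecm-comm analyze report --pairs 6 --pair-distance 4 --seed 7 -o report.json
```

`report.json` (abridged):

```json
{
  "same_vs_different": {
    "fraction_same_higher": 0.7666666666666667,
    "n_triplets": 120,
    "wilcoxon_p": 9.221311746136718e-13
  },
  "matchmaking": {
    "probability_correct": 0.25,
    "ranks": [38, 22, 1, 1, 19, 12, 11, 11, 5, 11, 1, 6],
    "pool_size": 50
  }
}
```

Reading this: in 76.7% of the 120 ordered triplets the communicating pair's
fluctuation correlation beat the cross-pair one (signed-rank p ≈ 1e-12
against the zero-median null), and correlation ranking placed the true
partner first among 50 candidates for 3 of the 12 cells — a 0.25 hit rate
against the 0.02 random baseline.  With contraction heterogeneity σ = 0 the
same pipeline returns chance-level fractions and non-significant tests:
heterogeneity is what makes a pair's signature unique.

The same analyses run on image stacks: `ecm-comm synth-image` generates a
synthetic 4D TIFF (two bright cells, fibrous speckle, correlated remodeling
fluctuations, local background modes, flicker, drift), and
`ecm-comm quantify` extracts border-corrected windowed intensity series in
the pair-aligned coordinate frame.  The library API (`ecmcomm.imaging`,
`ecmcomm.comms`) exposes every step individually.

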
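# mad2nmr

Residue-resolved kinetics of metamorphic-protein conformational conversion
from time-resolved 2D NMR, with chemical-shift fingerprinting, binding
analysis, relaxation profiling and ensemble-flexibility statistics.

## The problem

Mad2 is a metamorphic HORMA-domain protein: it interconverts between an
open conformer (O-Mad2, inactive) and a closed conformer (C-Mad2) that
topologically entraps a Mad2-interaction motif (MIM) peptide — the
rate-limiting step of mitotic-checkpoint-complex assembly. The spontaneous
O→C conversion takes about a day in solution; a Cdc20 MIM peptide
accelerates it nearly 50-fold. Because each backbone amide gives one peak
in a ¹H,¹⁵N correlation spectrum, a long series of fast 2D spectra turns
the conversion into hundreds of per-residue kinetic reporters: O-state
peaks decay, C-state peaks grow, and residues that leave the open state at
different rates reveal the order of structural events.

`mad2nmr` implements that analysis as a tested, reusable pipeline, plus a
synthetic-data generator with the same kinetic and statistical structure so
every stage is verifiable against known ground truth:

* **`synthetic`** — pseudo-3D intensity time series under two-state (O→C)
  or three-state (O→I→C) first-order kinetics with closed-form populations;
  titration, relaxation, and coordinate-ensemble generators.
* **`spectra`** — Sparky-style and delimited peak lists, intensity series
  containers, stride-1 sliding addition of consecutive spectra for
  signal-to-noise, peak extraction from 2D planes with overlap flagging.
* **`kinetics`** — the core: normalize O-decays to the first merged
  spectrum and C-rises to the last, fit `y = (y₀ − y_min)·exp(−kx) + y_min`
  per residue, build and compare rate profiles (median-ratio scaling flags
  residue-specific deviations under a global rate shift), score
  intermediate-state evidence, classify conformational state from
  tryptophan indole fingerprints.
* **`shifts`** — secondary chemical shifts
  `(δCα_obs − δCα_rc) − (δCβ_obs − δCβ_rc)`, weighted CSPs
  `√((Δδ_H·W_HN)² + (Δδ_N·W_N)²)` with `W_HN = 1, W_N = 0.16`, and K_D
  estimation on the single-site quadratic isotherm with honest lower-bound
  reporting for weak binders.
* **`relaxation`** — T1/T2 exponential fits on interleaved mixing-time
  series, hetNOE ratios, robust flagging of flexible segments.
* **`ensemble`** — Kabsch superposition, backbone RMSD series, iterated
  fit-to-average Cα RMSF over simulation repeats, Cβ contact probabilities
  with equilibration exclusion, per-residue value mapping into PDB
  B-factors.
* **`constructs`** — sequence variants as guarded edit operations
  (substitute / delete / replace), non-proline counts, average-mass
  computation.
* **`cli` / `config`** — a `mad2nmr` command with `simulate`, `merge`,
  `fit`, `compare`, `csp`, `kd`, `relax`, `ensemble`, `map` and `demo`
  subcommands, driven by a validated, re-runnable configuration.

## Worked example

```sh
$ mad2nmr demo --seed 1 --out-dir demo_out
acquisition: 120 spectra x 5 min = 10.0 h; 117 merged points at 5-min offsets
fitted rate ratio, 250-min vs 30-min completion: 8.33-fold (rounds to 8)
fitted fold-acceleration, 24-h vs 30-min completion: 48.0-fold
stochastic pipeline run: 20/20 O-decays converged; median fitted k 0.0099 1/min (truth 0.0100)
intermediate-consistent: False (median non-exponentiality 0.00e+00)
artifacts in demo_out
```

Reading the output: a loop-truncated variant completing conversion in
~250 min versus ~30 min for the fast variant corresponds to an 8-fold rate
difference once both decays are fitted through the merge/normalize/fit
pipeline; conversion in ~24 h without peptide versus <30 min with peptide
is a 48-fold acceleration. The stochastic run simulates a 20-residue
two-state conversion at 2% intensity noise, recovers the 0.0100 min⁻¹ rate
constant, and correctly reports no intermediate-state signature (a lagged,
non-exponential C-state appearance would raise the non-exponentiality
score and flip the verdict).

The same stages are available programmatically:

```python
from mad2nmr import (AcquisitionSpec, KineticModelSpec,
                     simulate_conversion_series, sliding_add,
                     normalize_conversion, build_rate_profile)
from mad2nmr.spectra import PeakAssignment

peaks = [PeakAssignment(1, "A", "O", 8.0, 120.0),
         PeakAssignment(1, "A", "C_empty", 8.3, 121.5)]
model = KineticModelSpec(k1=0.01, noise_sd=0.02,
                         amplitudes={(1, "O"): 1.0, (1, "C_empty"): 1.0})
series, truth = simulate_conversion_series(model, AcquisitionSpec(), peaks)
profile = build_rate_profile(normalize_conversion(sliding_add(series, 4)))
print(profile.o_fits[1].k)   # ~0.01
```

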
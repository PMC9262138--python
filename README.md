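# autosplice

Quantitative analysis of **negative autoregulatory splicing** — the circuit
motif in which a splicing factor (the motivating system is SRSF1 in HEK293
cells) promotes unproductive splicing of its own pre-mRNA, capping its own
synthesis as its concentration rises.

The package is for systems biologists who want to simulate, fit and
interrogate this motif without wet-lab data in hand: it ships an ODE model
of the autoregulated and unregulated circuit variants, Bayesian parameter
inference against induction time courses, single-cell trace feature
extraction with heterogeneity statistics, population-snapshot lognormal
fitting, steady-state perturbation analysis, and a CLIP-style target-load
correlation procedure — all exercised end to end on synthetic data with
known ground truth.

## The model

Species are unspliced pre-mRNA `u`, functional mRNA `m` and protein `p`,
for an ectopic (`ec`) and the endogenous (`en`) gene copy.  The unregulated
(cDNA) circuit is a linear cascade; the autoregulated (gDNA) circuit routes
production through splicing under Hill repression with substrate
competition (for x ∈ {ec, en}):

```
du_x/dt = α_x − β_u u_x
dm_x/dt = κ u_x · H(P_eff,x) − β_m m_x          H(P) = k^h / (k^h + P^h)
dp_x/dt = γ m_x − β_p p_x                        P_eff,x = u_x/(u_ec+u_en+R) · (p_ec+p_en)
```

`R` is the reservoir of competing substrate pre-mRNAs from other genes.
The motif's functional signatures, all reproduced and tested here:

* a **ceiling** on expression (log-log sensitivity of steady-state protein
  to production < 1, versus exactly 1 without feedback);
* **faster response** to induction at matched steady state;
* **reduced cell-cell heterogeneity** in plateau level and rise slope;
* **load adaptation**: steady-state factor level rises with `R`, and the
  factor's expression correlates with its targets' summed expression
  across tissues.

## Worked example

Simulate both circuits at high induction, extract per-cell trace features
from a synthetic movie, and compare heterogeneity:

```python
import numpy as np
from autosplice.model_core import ModelParameters, steady_state_feedback
from autosplice.synthetic_data import CellPopulationSpec, generate_single_cell_traces
from autosplice.trace_features import fit_trace_table, heterogeneity_stats
from autosplice.load_adaptation import sensitivity

p = ModelParameters()                       # study-scale defaults
ss = steady_state_feedback(p, p.alpha_ec_hi)
print(f"feedback plateau p_ec = {ss.p_ec:.1f} a.u.")
print(f"sensitivity d log p_total / d log alpha: feedback "
      f"{sensitivity(p, 'alpha_ec', p.alpha_ec_hi, response='p_total'):.3f}, "
      f"no-feedback "
      f"{sensitivity(p, 'alpha_ec', p.alpha_ec_hi, circuit='no_feedback'):.3f}")

# matched-median no-feedback control
p_nf = p.replace(alpha_ec_hi=ss.p_ec * p.beta_m * p.beta_p / p.gamma)
for circ, params in [("feedback", p), ("no_feedback", p_nf)]:
    spec = CellPopulationSpec(n_cells=100, cv_alpha=0.3, params_base=params, seed=7)
    traces, truth = generate_single_cell_traces(spec, circ, "high")
    stats = heterogeneity_stats(fit_trace_table(traces), seed=1)
    print(f"{circ:12s} dispersion(If) = {stats.dispersion('If'):.3f}, "
          f"dispersion(r) = {stats.dispersion('r'):.3f}")
```

prints

```
feedback plateau p_ec = 365.2 a.u.
sensitivity d log p_total / d log alpha: feedback -0.073, no-feedback 1.000
feedback     dispersion(If) = 0.060, dispersion(r) = 0.058
no_feedback  dispersion(If) = 0.260, dispersion(r) = 0.274
```

— at full induction the total factor level is essentially flat in the
production rate (|slope| ≈ 0.07 versus exactly 1 without feedback: the
expression ceiling), and the autoregulated population shows ~4x lower
cell-cell dispersion of both the plateau and the rise slope at matched
median output, even though both populations carry the same 30%
induction-strength variability.

Fitting works on condition-averaged curves.  `generate` + `fit` via the
CLI, or in Python:

```python
from autosplice.synthetic_data import generate_average_curves
from autosplice.inference import FitSpec, delay_screen, sample_posterior, posterior_summary

data, truth = generate_average_curves(ModelParameters(), seed=1)
spec = FitSpec(seed=1)
screen = delay_screen(data, spec)           # 65 delay pairs, short chains
sample = sample_posterior(data, spec, screen.best)
print(screen.best)                          # -> (8.25, 0.25)
print(posterior_summary(sample, ModelParameters()))
```

The summary reports medians and 95% intervals plus derived half-lives
(`ln2/β`) and the productive splicing flux fraction at the native
operating point.

## Command-line interface

Every stage is also a subcommand writing CSV/JSON artifacts plus a
provenance manifest (config hash, seed, version):

```bash
autosplice generate --what traces --n-cells 200 --seed 1 --out-dir out
autosplice features --traces out/traces.csv --out-dir out
autosplice generate --what curves --seed 1 --out-dir out
autosplice fit --curves out/curves.csv --skip-screen --out-dir out
autosplice adapt --variable reservoir --out-dir out
autosplice targets --records out/records.csv --tpm out/tpm.csv --factor FACTOR
```

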
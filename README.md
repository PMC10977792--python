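# gcgrn

Stochastic and deterministic models of the **BCL6–IRF4–BLIMP1** gene
regulatory network that drives germinal-center (GC) B cell differentiation
toward the plasmablast/plasma-cell (PB_PC) fate — for computational
biologists who want to simulate single-cell expression snapshots of the two
stages, analyse the network's steady states, and calibrate its parameters
against single-cell qPCR-style data.

## The model

Each gene *i* couples a two-state promoter to linear mRNA/protein kinetics:

    E_i : 0 ⇄ 1   at rates k_on,i (on) and k_off,i (off)
    M_i' = s0_i E_i − d0_i M_i
    P_i' = s1_i M_i − d1_i P_i

a piecewise-deterministic Markov process (PDMP): deterministic flow between
random promoter switches.  Regulation enters through the rates,

    k_on,i = k_on,i^min + k_on,i^max · (β_i Φ_i)/(1 + β_i Φ_i),
    Φ_i(P, Q) = ∏_s (1 + e^{θ_si} Q_s/H_si)/(1 + Q_s/H_si)
              · ∏_j (1 + e^{θ_ji} (x_j/H_ji)^γ)/(1 + (x_j/H_ji)^γ),

with `x_j` the fractional protein abundance of regulator *j*, `θ` the edge
strength/sign, `H` its threshold, `γ = 2`, and `k_off` obtained from the
same form with every `θ` negated.  The per-gene scalings `β` are calibrated
at initialisation so each gene starts exactly at its prescribed
(`k_on,init`, `k_off,init`).  The stimuli BCR (represses BCL6) and CD40
(activates IRF4) follow ramp–plateau–ramp time courses and drive the
transition from the GC expression pattern (BCL6 high, IRF4/BLIMP1 low) to
the PB_PC pattern (the reverse).

The package provides, on top of the simulator: the mean-field ODE
reduction (`⟨E⟩ = k_on/(k_on+k_off)`) with bistability detection, the
kinetic three-protein ODE reference model, grid-search and sweep
calibration machinery driven by the objective
`OF = Σ_nodes |Ω − Υ|/|Ω|` over the six gene × stage means, a binned
Kantorovich (1-D Wasserstein) distance with a model-to-model variability
study, and a generator of experiment-like single-cell qPCR datasets
(Et = 30 − Ct scale, exact per-gene dropout counts).  Parameter-table
versions I, II and III ship as YAML fixtures.  See `docs/methods.md` for
modeling choices and their rationale.

## Worked example

```python
from gcgrn import (load_parameter_version, default_schedules,
                   SimulationProtocol, simulate_dataset, detect_bistability)
from gcgrn.qpcr import dataset_means

# 200 cells, 500 h burn-in, stimuli, 500 h follow-up; GC and PB_PC snapshots
model = load_parameter_version("III")
protocol = SimulationProtocol(n_cells=200, seed=1)
dataset = simulate_dataset(model, default_schedules(), protocol).to_log2p1()
for (gene, stage), mean in sorted(dataset_means(dataset).items()):
    print(f"{gene:7s} {stage:6s} mean log2(mRNA+1) = {mean:5.2f}")

report = detect_bistability(load_parameter_version("I"), default_schedules())
print("version I bistable:", report.bistable)
print("pre-stimulus  mRNA:", report.pre_M.round(3))
print("post-stimulus mRNA:", report.post_M.round(3))
```

prints

```
BCL6    GC     mean log2(mRNA+1) =  8.33
BCL6    PB_PC  mean log2(mRNA+1) =  6.00
BLIMP1  GC     mean log2(mRNA+1) =  6.66
BLIMP1  PB_PC  mean log2(mRNA+1) = 13.23
IRF4    GC     mean log2(mRNA+1) =  2.57
IRF4    PB_PC  mean log2(mRNA+1) =  5.29
version I bistable: True
pre-stimulus  mRNA: [1.81819e+02 3.40000e-02 5.25000e-01]
post-stimulus mRNA: [49.623  8.46   5.669]
```

The tuned parameter set (version III) shows the stage switch in the
simulated single cells — BCL6 falls from GC to PB_PC while IRF4 and BLIMP1
rise — and the initial parameter set (version I) gives a mean-field system
with two stimulus-separated steady states: BCL6-high/IRF4-low/BLIMP1-low
before the stimuli (mRNA 182 / 0.034 / 0.52) and the reversed pattern
after (50 / 8.5 / 5.7).

A CLI mirrors the library:

```sh
gcgrn simulate --params III --n-cells 200 --seed 1 --out dataset.csv
gcgrn bistability --params I
gcgrn synth --seed 1 --out reference.csv
gcgrn kd --a dataset.csv --b reference.csv --gene IRF4 --stage GC
gcgrn fit-grid --base I --data reference.csv --subsample 1000 --seed 1 --out ranked.csv
```

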
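# spinshield

Entanglement preservation in geometrically structured spin clusters with
thermally damped buffer networks — an open-quantum-system toy model of the
phosphate group inside a Posner cluster, for people studying whether and how
molecular geometry can shield a nuclear-spin qubit from its environment.

## The model

Each cluster is a central spin-1/2 (phosphorus analogue) surrounded by `N`
buffer spins (oxygen analogues), coupled by an XX Hamiltonian (hbar = k_B = 1):

    H = sum_i (omega/2) sigma_z^(i)
      + sum_{pairs {i,j}} g_ij (sigma_x^(i) sigma_x^(j) + sigma_y^(i) sigma_y^(j)),

where the central spin couples to every buffer at strength `g` and the
buffer-buffer bonds are `g` or 0 according to a binary graph — either the
*star* (no buffer bonds) or the *complete* buffer network (for `N = 5`, the
complete graph minus one edge, forced by the central spin's position). Only
the buffers are damped, by local thermal baths at rate `gamma` with Planck
occupation `n(omega)`:

    d rho/dt = -i[H, rho] + sum_buffers gamma(1+n) D[sigma_-] + gamma n D[sigma_+].

Two such clusters, mutually uncoupled, start with their central spins in the
Bell state `(|01> + |10>)/sqrt(2)` and all buffers thermal. The package
computes:

- **log-negativity** `E_N(t) = log2(2 N(rho) + 1)` of the central pair and
  its **survival time** `t1` (when `E_N` stays below 1e-4 for good), per
  buffer geometry — the protection ranking;
- the **dressed picture**: diagonalizing the single-excitation buffer block
  `omega I + G A` (`G = 2g`) shows the connected network couples the central
  spin to a *single* dressed mode of strength `sqrt(N) G`, detuned by
  `(N-1) G` — the mechanism behind the protection;
- **non-Markovianity**: trace distance `D(t)` between evolved `|+>` / `|->`
  central states and the summed-backflow (BLP-style) witness;
- **coherence tools**: l1 and relative-entropy coherence, inter-block
  decomposition, and biorthogonal thermal states of non-Hermitian effective
  Hamiltonians (the superradiance/exciton-delocalization side).

Exact factorization (`Lambda_t x Lambda_t` on the Bell pair, via Choi
matrices) keeps the worst case at 7 qubits instead of 12; a brute-force
joint integration is retained as an oracle and agrees to ~1e-15.

## Worked example

```python
import numpy as np
from spinshield import (ModelParams, build_geometry, dressed_spectrum,
                        ExperimentConfig, run_survival_sweep)

params = ModelParams()  # omega=1, g=0.05, gamma=0.005, beta=5
for n in (2, 3, 4, 5):
    spec = dressed_spectrum(build_geometry(n, "maximal"), params)
    mags = np.abs(spec.couplings_in_g_units)
    kept = np.sort(mags[mags > 1e-10])[::-1]
    shift = (spec.dressed_frequencies.max() - params.omega) / params.g
    print(f"N={n}: dressed couplings {np.round(kept, 4)} G, "
          f"top frequency shift {shift:+.4f} g")

config = ExperimentConfig(geometries=((3, "vanishing"), (3, "maximal")),
                          t_max=3000.0, n_steps=600)
result = run_survival_sweep(config)
print(result.to_frame().to_string(index=False))
```

prints

```
N=2: dressed couplings [1.4142] G, top frequency shift +2.0000 g
N=3: dressed couplings [1.7321] G, top frequency shift +4.0000 g
N=4: dressed couplings [2.] G, top frequency shift +6.0000 g
N=5: dressed couplings [2.2264 0.2079] G, top frequency shift +7.2915 g
 cluster_size  n_buffer connectivity          t1
            4         3    vanishing 1202.003339
            4         3      maximal 1998.330551
```

Reading it: a complete buffer network funnels the central spin's `N` weak
couplings into one collective dressed mode (`sqrt(N) G`: 1.41, 1.73, 2.00
for N = 2, 3, 4; two residual modes, 2.2264 G and 0.2079 G, for the
N = 5 near-complete network) that is increasingly detuned from the central
spin. Consequently the Bell pair's entanglement survives markedly longer
with connected buffers — here t1 grows from ~1202 to ~1998 time units at
N = 3 — and across N = 2..5 the tetrahedral N = 4 complete network protects
longest. Full-sweep numbers, parameter meanings and caveats are in
`docs/methods.md`.

## Command line

```
spinshield sweep-survival --out results/           # survival-time table
spinshield simulate-entanglement --config cfg.yaml # E_N(t) CSVs (+ --plot)
spinshield non-markovianity --out results/         # D(t) + BLP witnesses
spinshield dressed-report -n 5                     # dressed spectrum JSON
spinshield fixtures --kind density_operator --seed 1
```

Configs are YAML/JSON with keys `params {omega, g, gamma, beta}`,
`geometries` (list of `[N, connectivity]`), `times {t_max, n_steps}`,
`threshold`. All dynamics are deterministic; identical configs give
byte-identical CSVs.

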
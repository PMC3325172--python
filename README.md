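# isilaw

Superstatistical analysis of cortical spike-train inter-spike-interval (ISI)
distributions: simulation of doubly-stochastic gamma firing, logarithmically
binned ISI histograms, power-law tail regression, beta-2 (generalized beta
prime) distribution fitting, decomposition into a gamma firing-rate law,
information measures, and constrained maximum-entropy solvers.

## The model

A neuron is treated as a stochastic interval generator: given an
instantaneous rate `ξ`, intervals follow a gamma law of shape `κ` and mean
`1/ξ`. When `ξ` itself fluctuates according to a gamma distribution of shape
`α` and mean `R`, the marginal ISI law is the beta-2 density

    p(T) = [Γ(α+κ)/(Γ(α)Γ(κ))] (1/τ) (T/τ)^(κ−1) (1+T/τ)^−(α+κ),   τ = α/(Rκ),

with power-law tail exponent `η = α+1`. Fitting this law to an ISI histogram
therefore decomposes the observed intervals into an intrinsic generator
(`κ`) and a latent rate distribution (`α`, `R`). The package also solves the
associated information-theoretic problems: maximizing the rate entropy under
a mean-rate constraint (exponential rate law, `α = 1`, `η = 2`), under an
additional bound on the conditional response entropy `H[T|Ξ]` (gamma rate
law, arbitrary `α`), and the contrast with discrete rate distributions,
whose ISI tails decay exponentially.

## CLI

All analysis steps are exposed as subcommands of `isilaw` (exit codes:
0 ok, 2 validation error, 3 numerical failure):

```sh
isilaw simulate --kappa 2 --alpha 1.91 --rate 10 --n 100000 --seed 1 --out train.txt
isilaw histogram --in train.txt --out hist.tsv
isilaw tailfit   --in hist.tsv --scale both --out tail.json
isilaw fit-beta2 --in hist.tsv --out fit.json
isilaw decompose --fit fit.json --out rates.json
isilaw entropy   --fit fit.json --out entropy.json
isilaw maxent    --mode cmfe --r 10 --i 5.8 --kappa 2 --grid --out sol.json
isilaw analyze   --in train.txt --out report.json
isilaw fixtures  --out-dir fixtures/ --seed 0
```

Spike files are plain text (one ascending timestamp in seconds per line);
simulated trains carry a JSON sidecar with the generation parameters and
true per-interval rates. Histograms are TSV, reports JSON.

## Layout

| module | contents |
| --- | --- |
| `isilaw.simulate` | gamma generator, gamma/discrete rate models, spike-train simulators |
| `isilaw.histogram` | ISI extraction, 80-bin logarithmic histogram, stationarity split, cell typing |
| `isilaw.tailfit` | tail regression in double-/semi-log coordinates, power-law verdict |
| `isilaw.beta2` | beta-2 density, moments, binned least-squares fitting |
| `isilaw.superstat` | mixture quadrature, rate-law decomposition, large-`α` limit |
| `isilaw.entropy` | `H[Ξ]`, generator entropy `S`, `H[T|Ξ]`, `H[T]`, mutual information |
| `isilaw.maxent` | constrained entropy maximization (analytic + grid), duality check |
| `isilaw.pipeline` | per-neuron end-to-end analysis, fixture battery |
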
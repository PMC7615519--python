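# streamfdr

Online multiple hypothesis testing for streaming p-values: per-hypothesis
test levels and rejection decisions under online FDR control (LORD, LORD++,
SAFFRON, ADDIS, monotone alpha-investing) or online FWER control
(alpha-spending, online Šidák), with auditable alpha-wealth accounting,
bounded (finite-horizon, renormalized) variants, offline comparators
(Benjamini–Hochberg, uncorrected), error-rate estimators
(FDR/mFDR/FDX/FWER/power), and a Gaussian simulation testbed.

## Library quick start

```python
from streamfdr import make_policy, stampede_fixture

stream = stampede_fixture()                      # packaged 7-arm example
policy = make_policy("saffron", alpha=0.05, bound=20)
log = policy.run(stream.pvals, ids=stream.ids)
log.rejected_ids      # ['C', 'G']
log.next_level        # level the 8th hypothesis would get (~0.0165)
```

Every run produces a `DecisionLog` with per-hypothesis records
`(index, id, pval, alpha, reject, wealth)` plus the level that would apply
to the next hypothesis. The underlying `StreamState` additionally records
the generalized alpha-investing ledger (price, payout, candidate/selection
indicators per step).

Simulation testbed:

```python
from streamfdr import SimulationConfig, run_experiment

config = SimulationConfig(T=1000, replicates=2000, seed=1)
table = run_experiment(config, ["lordpp", "saffron", "addis"],
                       pi1_grid=[0.1, 0.3, 0.5])
```

## CLI

```bash
# run an online policy over a CSV stream (columns: id,pval[,batch])
streamfdr run --alg saffron --alpha 0.05 --bound 20 \
    --input pvals.csv --output log.csv

# Gaussian-mixture simulation experiment
streamfdr simulate --T 1000 --pi1 0.1,0.3,0.5 --reps 2000 --seed 1 \
    --algs lordpp,saffron,addis --out results.csv

# packaged fixtures
streamfdr fixtures list
streamfdr fixtures cat stampede
```

Flags beat values from `--config cfg.json`, which beat the defaults.

## Layout

- `streamfdr.spending` — spending sequences (default LORD schedule,
  power laws, uniform), bounded truncation with renormalization
- `streamfdr.core` — decision rule, wealth update, GAI++ payout cap,
  FDP estimators, decision logs
- `streamfdr.fdr` — online FDR policies and the stream runner
- `streamfdr.fwer` — online FWER policies (alpha-spending, Šidák)
- `streamfdr.offline` — BH step-up and uncorrected comparators
- `streamfdr.metrics` — FDR/mFDR/FDX/FWER/power estimators with MC SEs
- `streamfdr.simulate` — Gaussian testbed and experiment grids
- `streamfdr.io` / `streamfdr.cli` — CSV readers/writers, fixtures, CLI
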
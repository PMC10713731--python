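#!/usr/bin/env python
"""Simulate a desk-scale metabolite-vs-ovarian-cancer study.

Generates summary statistics for a panel of 10 synthetic metabolite
exposures against 2 cancer phenotypes, with a handful of planted causal
effects and the rest null, plus an LD panel and a batch manifest.
Everything downstream (02_run_mr_batch.py) consumes only these files.

Writes results/sim_study/{*.tsv, manifest.tsv, truth.tsv, ld.tsv}.
"""

from pathlib import Path

import pandas as pd

import metabomr as mm
from metabomr.sumstats_io import write_sumstats

BASE_SEED = 20240915
OUT = Path(__file__).resolve().parents[1] / "results" / "sim_study"

EXPOSURES = [f"metabolite_{i:02d}" for i in range(10)]
OUTCOMES = ["overall_oc", "serous_oc"]

# planted causal log-odds per SD of metabolite; every other pair is null
TRUE_THETA = {
    ("metabolite_00", "overall_oc"): -0.35,
    ("metabolite_01", "overall_oc"): 0.25,
    ("metabolite_02", "serous_oc"): -0.30,
    ("metabolite_03", "overall_oc"): -0.20,
}

# instrument counts vary across metabolites, like real mQTL panels
K_INSTRUMENTS = [1, 4, 3, 6, 2, 4, 8, 3, 5, 2]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest, truth_rows = [], []
    for e_idx, exposure in enumerate(EXPOSURES):
        for outcome in OUTCOMES:
            theta = TRUE_THETA.get((exposure, outcome), 0.0)
            cfg = mm.SimulationConfig(
                k_instruments=K_INSTRUMENTS[e_idx],
                n_null_snps=10,
                theta=theta,
                effect_sd=0.15,  # strong planted mQTLs: all reach 5e-8
                seed=mm.derive_seed(BASE_SEED, exposure, outcome),
            )
            exp_rec, out_rec, truth = mm.simulate_sumstats(cfg)
            ep = OUT / f"{exposure}__{outcome}__exposure.tsv"
            op = OUT / f"{exposure}__{outcome}__outcome.tsv"
            write_sumstats(exp_rec, ep)
            write_sumstats(out_rec, op)
            manifest.append({
                "exposure": exposure, "outcome": outcome,
                "exposure_path": ep.name, "outcome_path": op.name,
            })
            truth_rows.append({
                "exposure": exposure, "outcome": outcome,
                "theta": theta, "k_instruments": cfg.k_instruments,
            })
    pd.DataFrame(manifest).to_csv(OUT / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(OUT / "truth.tsv", sep="\t", index=False)
    ld_cfg = mm.SimulationConfig(k_instruments=max(K_INSTRUMENTS), n_null_snps=10)
    mm.simulate_ld(ld_cfg).to_square_file(OUT / "ld.tsv")
    n_causal = sum(1 for t in truth_rows if t["theta"] != 0)
    print(f"wrote {len(manifest)} exposure-outcome pairs to {OUT}")
    print(f"{n_causal} pairs carry a true causal effect; the rest are null")


if __name__ == "__main__":
    main()
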
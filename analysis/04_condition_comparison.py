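#!/usr/bin/env python
"""Basal vs phosphoinositide-stimulated extraction: fitted fold changes.

Generates paired synthetic datasets (basal: K1 = 0.8 μM, k+2 = 0.05 s⁻¹;
stimulated: 0.4 μM, 0.1 s⁻¹ — membrane binding tightens, transfer speeds
up), fits both, and reports the fold changes of K1, k+2 and the
second-order efficiency k+2/K1 (truth: 2 × 2 = 4).  Also runs the plateau
check on noiseless progress curves: stimulation changes rates, not the
final extracted amount.  Writes results/condition_folds.csv and
results/condition_comparison.json.
"""

import argparse
import json
from pathlib import Path

from sterolex.fitting import plateau_check
from sterolex.signals import dhe_transport_amount
from sterolex.studies import condition_fold_study
from sterolex.synth import NoiseModel, ScenarioConfig, generate_extraction_trace

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--pairs", type=int, default=20)
    args = parser.parse_args()

    folds = condition_fold_study(n_pairs=args.pairs, base_seed=args.seed)
    RESULTS.mkdir(exist_ok=True)
    folds.to_csv(RESULTS / "condition_folds.csv", index=False)
    med = folds.median(numeric_only=True)
    print(f"over {args.pairs} seeded dataset pairs (median):")
    print(f"  K1 fold (basal/stim):          {med['K1_fold_basal_over_stim']:.2f}")
    print(f"  k+2 fold (stim/basal):         {med['k_plus2_fold_stim_over_basal']:.2f}")
    print(f"  k+2/K1 fold (stim/basal):      {med['second_order_fold_stim_over_basal']:.2f}")

    scenario = ScenarioConfig()
    zero = NoiseModel(0.0, 0.0, 0)
    traces = {}
    for cond in ("basal", "plus_PIP"):
        trace, cal = generate_extraction_trace(scenario, cond, zero)
        traces[cond] = trace.with_signal(dhe_transport_amount(trace.signal, cal))
    plateau = plateau_check(traces["basal"], traces["plus_PIP"])
    summary = {
        "median_folds": {k: float(v) for k, v in med.items() if k != "pair"},
        "final_extraction_basal_uM": plateau.final_basal,
        "final_extraction_stim_uM": plateau.final_stim,
        "final_extraction_ratio": plateau.ratio,
    }
    (RESULTS / "condition_comparison.json").write_text(json.dumps(summary, indent=2))
    print(f"\nfinal extracted amount: basal {plateau.final_basal:.3f} μM, "
          f"stimulated {plateau.final_stim:.3f} μM (ratio "
          f"{plateau.ratio:.3f}) — stimulation accelerates extraction "
          "without changing its extent")


if __name__ == "__main__":
    main()
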
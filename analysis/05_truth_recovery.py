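#!/usr/bin/env python
"""Truth-recovery experiments: can the pipeline see through its own biases?

(a) sampling-bias experiment: a non-peak band is oversampled 3:1; raw
    richness should follow the bias while coverage-standardized (SQS)
    richness retains the true peak band.
(b) proxy-recovery experiment: per-band richness generated from TurtBF; the
    model comparison should hand TurtBF the Akaike weight.

Writes results/recovery/{bias_replicates.csv, proxy_replicates.csv,
summary.json}.
"""

import argparse
import json
from pathlib import Path

from paleolbg.synthetic_data import proxy_model_recovery, sampling_bias_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--bias-replicates", type=int, default=100)
    parser.add_argument("--proxy-replicates", type=int, default=200)
    parser.add_argument("--trials", type=int, default=500)
    parser.add_argument("--quorum", type=float, default=0.4)
    parser.add_argument("--out", type=Path, default=Path("results/recovery"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    bias = sampling_bias_experiment(
        n_replicates=args.bias_replicates, q=args.quorum, trials=args.trials, seed=args.seed
    )
    proxy = proxy_model_recovery(n_replicates=args.proxy_replicates, seed=args.seed + 1)
    bias.to_csv(args.out / "bias_replicates.csv", index=False)
    proxy.to_csv(args.out / "proxy_replicates.csv", index=False)

    summary = {
        "raw_peak_moves_to_biased_band": float(bias["raw_on_biased"].mean()),
        "raw_retains_true_peak": float(bias["raw_retains"].mean()),
        "sqs_retains_true_peak": float(bias["sqs_retains"].mean()),
        "proxy_model_win_rate": float((proxy["winner"] == "TurtBF").mean()),
    }
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"bias experiment ({args.bias_replicates} replicates, 3:1 oversampling, "
          f"q={args.quorum}, T={args.trials}):")
    print(f"  raw richness peak lands on the oversampled band in "
          f"{summary['raw_peak_moves_to_biased_band']:.0%} of replicates")
    print(f"  raw richness retains the true peak in {summary['raw_retains_true_peak']:.0%}")
    print(f"  SQS retains the true peak in {summary['sqs_retains_true_peak']:.0%}")
    print(f"proxy experiment ({args.proxy_replicates} replicates): generating "
          f"covariate wins the Akaike weight in {summary['proxy_model_win_rate']:.0%}")


if __name__ == "__main__":
    main()
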
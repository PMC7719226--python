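"""Sister-triplet dS contrasts under two mutation-rate scenarios.

Simulates triplets with a shared split time and (a) equal sister rates,
(b) a twofold rate difference, estimates per-branch dS via the additive
triplet decomposition, applies the strict retention window
0.00005 < dS < 1, and summarizes the log dS contrasts — which cancel
the divergence time and so estimate log(u1/u2) directly.
"""

import json
import math
from pathlib import Path

import numpy as np

from mitodiv import sister_pairs as sp
from mitodiv.synthetic_data import TripletSimConfig, simulate_triplets

ROOT = Path(__file__).resolve().parents[1]


def run_scenario(rate_ratio: float, seed: int) -> dict:
    alns, _ = simulate_triplets(
        TripletSimConfig(n_triplets=80, divergence=0.08,
                         rate_ratio=rate_ratio, seed=seed)
    )
    records = []
    for aln in alns:
        ds1, ds2 = sp.triplet_branch_ds(aln)
        trip = sp.Triplet(aln.sequence_ids[0], aln.sequence_ids[1],
                          aln.sequence_ids[2], aln.genes[0][0])
        records.append(sp.TripletRecord(triplet=trip, ds1=ds1, ds2=ds2))
    kept = sp.filter_ds(records)
    contrasts = [c["ds"] for rec in kept
                 if "ds" in (c := sp.pair_contrasts(rec))]
    arr = np.asarray(contrasts)
    return {
        "rate_ratio": rate_ratio,
        "n_simulated": len(records),
        "n_retained": len(kept),
        "mean_log_ds_contrast": float(arr.mean()),
        "se": float(arr.std(ddof=1) / math.sqrt(len(arr))),
        "expected": math.log(rate_ratio),
        "table": sp.triplet_table(records),
    }


def main() -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    summaries = []
    for rate_ratio, seed in [(1.0, 11), (2.0, 12)]:
        s = run_scenario(rate_ratio, seed)
        table = s.pop("table")
        table.to_csv(out / f"triplets_ratio{rate_ratio:g}.tsv", sep="\t",
                     index=False)
        summaries.append(s)
        print(f"rate ratio {rate_ratio:g}: {s['n_retained']}/{s['n_simulated']}"
              f" retained; mean log dS contrast {s['mean_log_ds_contrast']:+.3f}"
              f" +- {s['se']:.3f} (expected {s['expected']:+.3f})")
    (out / "triplet_summary.json").write_text(json.dumps(summaries, indent=2))


if __name__ == "__main__":
    main()
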
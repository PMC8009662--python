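"""Post-division crescent persistence under two decay conditions.

Simulates two groups of post-ACD traces (40-min frames) whose true crescent
disappearance times differ by 120 min on average, fits every frame, applies
the detectability rule, and compares group persistence — the analysis that,
on real time-lapse data, links crescent persistence in the large daughter to
the division behaviour of its meristemoid sister.
"""

import argparse
from pathlib import Path

import numpy as np

from stomapolar import io, synth
from stomapolar.persistence import (PersistenceTrace, compare_persistence_groups,
                                    measure_persistence, normalized_amplitude_curve)
from stomapolar.polarity import measure_polarity


def _group(name, offset, n, seed):
    results, curves = [], []
    for i in range(n):
        rng = np.random.default_rng(seed + i)
        dt = float(rng.uniform(140.0, 300.0)) + offset
        ts = synth.SynthTimeSeriesParams(frame_interval=40.0, n_frames=13,
                                         half_life=240.0, disappearance_time=dt,
                                         initial_amplitude=80.0, seed=seed + i)
        times, profiles, _ = synth.synthesize_decay_profiles(ts, baseline=20.0,
                                                             noise_sd=8.0)
        trace = PersistenceTrace(i, times,
                                 [measure_polarity(p) for p in profiles])
        results.append(measure_persistence(trace))
        curves.append(normalized_amplitude_curve(trace))
    return results, np.array(curves)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-per-group", type=int, default=25)
    ap.add_argument("--out", type=Path, default=Path("results/persistence"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    short, curves_s = _group("short", 0.0, args.n_per_group, 10_000 + args.seed)
    long_, curves_l = _group("long", 120.0, args.n_per_group, 20_000 + args.seed)
    io.write_persistence_table(args.out / "persistence_short.csv", short)
    io.write_persistence_table(args.out / "persistence_long.csv", long_)
    np.savetxt(args.out / "normalized_amplitude_short.csv", curves_s,
               delimiter=",", fmt="%.4f")

    cmp = compare_persistence_groups(short, long_)
    print(f"n = {cmp.n_a}/{cmp.n_b} uncensored traces per group "
          f"({cmp.n_censored_a}/{cmp.n_censored_b} censored)")
    print(f"mean persistence difference: {cmp.mean_difference:.0f} min "
          f"(true offset 120 min), rank-sum p = {cmp.p_value:.2e}")
    print(f"outputs -> {args.out}")


if __name__ == "__main__":
    main()
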
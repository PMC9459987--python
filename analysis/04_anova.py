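#!/usr/bin/env python
"""Factorial ANOVA cascade on the benchmark errors.

Reads the realization table written by 03_estimator_benchmark.py, runs the
three-way ANOVA on the per-realization absolute errors of MNF and MDF,
descends into two-way (per SNR) and one-way (per duration) analyses where
interactions are significant, and applies Tukey HSD post-hoc comparisons
on the method factor.
"""

from pathlib import Path

import pandas as pd

from emgfatigue import anova_cascade

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = OUT / "realizations.csv"
    if not path.exists():
        raise SystemExit("run analysis/03_estimator_benchmark.py first")
    frame = pd.read_csv(path)

    for param in ("mnf", "mdf"):
        response = f"err_{param}"
        cascade = anova_cascade(frame, response)
        cascade.three_way.table.to_csv(OUT / f"anova_three_way_{param}.csv")
        p3 = cascade.three_way.p("method x duration_ms x snr_db")
        print(f"\n{param.upper()}: three-way interaction p = {p3:.3g}")
        print(cascade.three_way.table.round(4).to_string())

        for snr, aov in cascade.two_way.items():
            aov.table.to_csv(OUT / f"anova_two_way_{param}_snr{snr:g}.csv")
        if cascade.two_way:
            print(f"  descended into {len(cascade.two_way)} two-way ANOVAs (per SNR)")
        print(f"  one-way method ANOVAs run: {len(cascade.one_way)}")

        posthoc = []
        for (snr, dur), ph in cascade.posthoc.items():
            posthoc.append(ph.assign(snr_db=snr, duration_ms=dur))
        if posthoc:
            tukey = pd.concat(posthoc, ignore_index=True)
            tukey.to_csv(OUT / f"tukey_{param}.csv", index=False)
            n_sig = int(tukey["sig_0.05"].sum())
            print(
                f"  Tukey HSD: {len(tukey)} pairwise comparisons, "
                f"{n_sig} significant at 0.05 -> tukey_{param}.csv"
            )


if __name__ == "__main__":
    main()
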
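#!/usr/bin/env python
"""Bar charts of the MAE benchmark (one panel per SNR level).

Mirrors the study's presentation: grouped bars of per-method MAE with SD
whiskers, split by duration, one figure per (parameter, SNR).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fig_dir = OUT / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    written = 0
    for param in ("mnf", "mdf"):
        path = OUT / f"mae_{param}.csv"
        if not path.exists():
            raise SystemExit("run analysis/03_estimator_benchmark.py first")
        mae = pd.read_csv(path)
        for snr, sub in mae.groupby("snr_db"):
            pivot = sub.pivot(index="duration_ms", columns="method", values="mae_hz")
            sd = sub.pivot(index="duration_ms", columns="method", values="sd_hz")
            ax = pivot.plot.bar(yerr=sd, capsize=2, figsize=(9, 4), width=0.8)
            ax.set_xlabel("signal duration (ms)")
            ax.set_ylabel(f"{param.upper()} mean absolute error (Hz)")
            ax.set_title(f"{param.upper()} error by method, SNR = {snr:g} dB")
            ax.figure.tight_layout()
            ax.figure.savefig(fig_dir / f"mae_{param}_snr{snr:g}dB.png", dpi=150)
            plt.close(ax.figure)
            written += 1
    print(f"wrote {written} figures to {fig_dir}")


if __name__ == "__main__":
    main()
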
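#!/usr/bin/env python
"""Generate example synthetic sEMG realizations and verify the generator.

Produces one clean and one noisy realization per study duration, checks
the achieved SNR and the spectral fidelity of the shaping filter, and
writes a summary table plus a few example signal files.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from emgfatigue import (
    IdealSpectrum,
    add_noise,
    design_shaping_filter,
    generate_clean,
    save_signal,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main() -> None:
    spec = IdealSpectrum()
    OUT.mkdir(exist_ok=True)
    sig_dir = OUT / "example_signals"
    sig_dir.mkdir(exist_ok=True)

    rows = []
    for i, duration in enumerate(range(250, 2001, 250)):
        n = int(round(duration * spec.f_s / 1000))
        shaping = design_shaping_filter(spec, length=min(n, 512))
        clean = generate_clean(duration, spec, seed=SEED + i, shaping=shaping)
        noisy = add_noise(clean, 10.0, seed=SEED + 100 + i)
        noise = noisy.samples - clean.samples
        achieved = 10 * np.log10(np.mean(clean.samples**2) / np.mean(noise**2))
        rows.append(
            {
                "duration_ms": duration,
                "n_samples": clean.n_samples,
                "clean_power": np.mean(clean.samples**2),
                "target_snr_db": 10.0,
                "achieved_snr_db": achieved,
            }
        )
        if duration in (250, 2000):
            save_signal(sig_dir / f"example_T{duration}ms_snr10dB.txt", noisy)

    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "simulation_check.csv", index=False)
    print("Simulated one clean + one 10 dB realization per study duration:")
    print(frame.round(4).to_string(index=False))
    print(
        "  achieved SNR is exact by construction "
        f"(max |deviation| = {np.abs(frame.achieved_snr_db - 10).max():.2e} dB)"
    )
    print(f"-> {OUT / 'simulation_check.csv'}, example signals in {sig_dir}")


if __name__ == "__main__":
    main()
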
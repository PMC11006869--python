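#!/usr/bin/env python
"""Simulate flash-photolysis surfaces for the sodium-pumping photocycle.

Generates ΔA(t, λ) for the default five-step sequential scheme
(K1 → K2 → M → O1 → O2 → ground) under a sodium-replete condition, with and
without measurement noise, and writes them under results/ as CSV + JSON
sidecars for the downstream lifetime analysis.
"""

from pathlib import Path

from ndqkit import kinetics_lda as lda
from ndqkit import synthetic_data as sd

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    scheme = sd.ernar_scheme()
    for name, noise in [("ta_clean", 0.0), ("ta_noisy", 0.002)]:
        cfg = sd.SimulationConfig(
            seed=1,
            noise_sigma=noise,
            time_grid=(1e-6, 25, 1e-7, 30.0),
            wavelength_grid=(330.0, 700.0, 10.0),
        )
        ds = sd.simulate_transient_dataset(scheme, cfg)
        path = OUT / f"{name}.csv"
        lda.write_transient_csv(ds, path)
        print(
            f"{name}: {ds.times.size} time points x {ds.wavelengths.size} wavelengths, "
            f"noise sigma {noise} -> {path}"
        )
    print(
        "scheme lifetimes (s): "
        + ", ".join(f"{n}={t:g}" for n, t in zip(scheme.intermediate_names, scheme.lifetimes))
    )


if __name__ == "__main__":
    main()
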
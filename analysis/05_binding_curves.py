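"""Laurdan-GP binding curves: generate, add noise, refit the Hill model.

Simulates GP titrations (0.125–16 μM doubling series) for three ground
truths spanning the affinity range reported for hairpin-bearing
constructs (K_D ≈ 1.5–3.3 μM), with realistic measurement noise, and
refits each with the four-parameter Hill model to recover K_D and the
apparent cooperativity.  Also demonstrates the noise-free round trip.
"""

from pathlib import Path

import pandas as pd

from memhairpin import spectro, synth

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

GROUND_TRUTH = [
    ("high_affinity", synth.CurveSimSpec(gp0=0.04, delta_gp=0.28, kd=1.5,
                                         n_hill=1.2, noise_sd=0.01, seed=11)),
    ("mid_affinity", synth.CurveSimSpec(gp0=0.05, delta_gp=0.30, kd=2.0,
                                        n_hill=1.5, noise_sd=0.01, seed=12)),
    ("low_affinity", synth.CurveSimSpec(gp0=0.06, delta_gp=0.25, kd=3.3,
                                        n_hill=1.0, noise_sd=0.01, seed=13)),
]


def main() -> None:
    rows = []
    for name, spec in GROUND_TRUTH:
        df = synth.generate_binding_curve(spec)
        fit = spectro.fit_hill(spectro.BindingCurve(df.concentration_uM.values,
                                                    df.gp.values))
        rows.append({"curve": name, "kd_true_uM": spec.kd,
                     "kd_fit_uM": fit.kd, "kd_se_uM": fit.se["kd"],
                     "n_true": spec.n_hill, "n_fit": fit.n,
                     "gp0_fit": fit.gp0, "delta_gp_fit": fit.delta_gp,
                     "low_confidence": fit.low_confidence})
        print(f"{name}: K_D true {spec.kd:.2f} μM → fit "
              f"{fit.kd:.2f} ± {fit.se['kd']:.2f} μM, n = {fit.n:.2f}")
    pd.DataFrame(rows).to_csv(OUT / "hill_fits.csv", index=False)

    clean = synth.generate_binding_curve(synth.CurveSimSpec(noise_sd=0.0))
    fit = spectro.fit_hill(spectro.BindingCurve(clean.concentration_uM.values,
                                                clean.gp.values))
    print(f"noise-free round trip: K_D recovered to "
          f"{abs(fit.kd - 2.0) / 2.0:.2e} relative error")
    print(f"wrote {OUT / 'hill_fits.csv'}")


if __name__ == "__main__":
    main()
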
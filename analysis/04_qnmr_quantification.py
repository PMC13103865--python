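"""Water-referenced qNMR quantification: round trip and worked example.

Builds integral tables for representative solution compositions with the
generator (exact inverse of the molality formula), recovers the
molalities, and reports the recovery error with and without integral
noise.  Writes results/qnmr_recovery.csv.
"""

from pathlib import Path

import pandas as pd

import xanthsol as xs
from xanthsol.solution import M_W
from xanthsol.synthetic import generate_nmr_table

BASE = Path(__file__).resolve().parent.parent / "results"

COMPOSITIONS = {
    "caffeine_saturated": {"caffeine": 0.106},
    "caffeine_ferulate_mix": {"caffeine": 2.0, "ferulate": 1.65},
    "theobromine_best": {"theobromine": 0.55, "ferulate": 3.7},
}
PROTONS = {
    "caffeine": {"H8": 1, "NMe1": 3, "NMe3": 3, "NMe7": 3},
    "theobromine": {"H8": 1, "NMe1": 3, "NMe3": 3},
    "ferulate": {"Ha": 1, "Hb": 1, "H2": 1, "OMe": 3},
}


def main() -> None:
    BASE.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, molal in COMPOSITIONS.items():
        protons = {c: PROTONS[c] for c in molal}
        for noise in (0.0, 0.01):
            table = generate_nmr_table(molal, protons, noise_sd=noise,
                                       seed=5)
            out = xs.molality_from_integrals(table)
            for comp, m_true in molal.items():
                rel = abs(out[comp] - m_true) / m_true
                rows.append({"sample": name, "compound": comp,
                             "noise_sd": noise, "true": m_true,
                             "recovered": round(out[comp], 6),
                             "rel_error": f"{rel:.2e}"})
        table.to_csv(BASE / f"qnmr_table_{name}.csv", index=False)
        clean = {c: xs.molality_from_integrals(
            generate_nmr_table(molal, protons))[c] for c in molal}
        print(f"{name}: " + ", ".join(
            f"{c} {clean[c]:.4g} mol/kg (true {molal[c]})" for c in molal))
    df = pd.DataFrame(rows)
    df.to_csv(BASE / "qnmr_recovery.csv", index=False)
    worst = df[df.noise_sd == 0.0]["rel_error"].map(float).max()
    print(f"zero-noise worst relative error: {worst:.2e}")
    print(f"equimolal identity: per-proton solute integral equal to the "
          f"per-proton water integral reads 1/M_W = {1 / M_W:.3f} mol/kg")
    print(f"wrote {BASE / 'qnmr_recovery.csv'}")


if __name__ == "__main__":
    main()
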
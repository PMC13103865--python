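"""Build the synthetic periodic boxes the stacking analyses run on.

Generates three kinds of systems at desk scale (32-40 A cubic boxes):
a dilute monomeric xanthine solution, a concentrated self-aggregated one
(pure-xanthine fibrils), and agent-containing boxes where benzene-like
agents intercalate into the fibrils while pyridine-like agents end-cap
them.  Writes XYZ + species sidecar + ground truth under results/boxes/.
"""

from pathlib import Path

import xanthsol as xs
from xanthsol.frames import write_species_map
from xanthsol.synthetic import write_box_config, write_ground_truth_csv

OUT = Path(__file__).resolve().parent.parent / "results" / "boxes"

SYSTEMS = {
    "dilute": xs.BoxSpec(box_edge=32.0, n_free_xanthine=3, n_water=1000,
                         seed=70),
    "concentrated": xs.BoxSpec(box_edge=32.0, fibril_plan=[("XAN",) * 6] * 3,
                               n_water=1000, seed=71),
    "intercalated": xs.BoxSpec(
        box_edge=36.0,
        fibril_plan=[("XAN", "BZA", "XAN", "BZA", "XAN"),
                     ("XAN", "XAN", "BZA", "XAN")],
        n_free_xanthine=2, n_water=800, n_cation=4, seed=72,
        tilt_sd=3.0, lateral_jitter_sd=0.2),
    "end_capped": xs.BoxSpec(
        box_edge=36.0,
        fibril_plan=[("PYA", "XAN", "XAN", "XAN", "PYA"),
                     ("PYA", "XAN", "XAN", "XAN")],
        n_free_xanthine=2, n_water=800, n_cation=4, seed=73,
        tilt_sd=3.0, lateral_jitter_sd=0.2),
    "inert_agent": xs.BoxSpec(
        box_edge=36.0, fibril_plan=[("XAN",) * 5] * 2,
        n_free_agent=6, free_agent_species="ALI", n_water=800, seed=74),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for name, spec in SYSTEMS.items():
        frame, truth = xs.generate_box(spec)
        xs.write_xyz(frame, OUT / f"{name}.xyz")
        write_species_map(frame, OUT / f"{name}.species.csv")
        write_ground_truth_csv(frame, truth, OUT / f"{name}.truth.csv")
        write_box_config(spec, OUT / f"{name}.spec.yaml")
        n_planted = sum(1 for k in truth.planted_k.values() if k > 0)
        print(f"{name}: {frame.n_molecules} molecules "
              f"({frame.count_role('xanthine')} xanthine, "
              f"{frame.count_role('agent')} agent, "
              f"{frame.count_role('water')} water); "
              f"{n_planted}/{len(truth.planted_k)} xanthines have planted "
              f"agent contacts")


if __name__ == "__main__":
    main()
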
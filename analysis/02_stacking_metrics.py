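"""Neighbor census, P(k), per-agent efficiency and aggregates per box.

Reads the boxes written by 01_simulate_boxes.py back through the XYZ path
(so the analysis sees exactly what a user's trajectory would look like)
and writes one metrics table per system plus a cross-system summary.

Expected findings: the concentrated box out-crowds the dilute one in
xanthine-xanthine neighbors and loses first-shell waters; the
intercalated box shows interior agents and a high P(k>0); the end-capped
box shows terminal agents; the inert-agent box stays at P(0) = 1.
"""

from pathlib import Path

import pandas as pd

import xanthsol as xs
from xanthsol.frames import read_species_map

BASE = Path(__file__).resolve().parent.parent / "results"
BOXES = BASE / "boxes"


def main() -> None:
    rows = []
    for spec_file in sorted(BOXES.glob("*.xyz")):
        name = spec_file.stem
        smap = read_species_map(BOXES / f"{name}.species.csv")
        traj = xs.read_xyz(spec_file, smap)
        frame = traj[0]
        census = xs.neighbor_census(traj)
        occ = xs.classify_axial(traj)
        dist = xs.config_distribution(occ)
        n_x = frame.count_role("xanthine")
        n_a = frame.count_role("agent")
        eff = (xs.agent_efficiency(dist, n_x, n_a).efficiency
               if n_a else float("nan"))
        aggs = xs.detect_aggregates(frame)
        n_fib = sum(a.is_fibril for a in aggs.aggregates)
        interior = sum(a.n_interior_agents for a in aggs.aggregates)
        ends = sum(a.n_end_agents for a in aggs.aggregates)
        rows.append({
            "system": name, "n_xanthine": n_x, "n_agent": n_a,
            "mean_xan_neighbors": round(census.mean_xanthine, 3),
            "mean_waters": round(census.mean_water, 3),
            "P0": round(dist.p[0], 3), "P1": round(dist.p[1], 3),
            "P2": round(dist.p[2], 3), "P3": round(dist.p[3], 3),
            "efficiency": round(eff, 3) if n_a else "",
            "n_fibrils": n_fib, "interior_agents": interior,
            "end_agents": ends,
        })
        print(f"{name}: {census.mean_xanthine:.2f} xanthine / "
              f"{census.mean_water:.2f} water neighbors per xanthine; "
              f"P(k)={[round(float(p), 2) for p in dist.p]}; "
              f"{n_fib} fibril(s), {interior} interior / {ends} end agents")
    df = pd.DataFrame(rows)
    out = BASE / "stacking_metrics.csv"
    df.to_csv(out, index=False)
    print(f"\nwrote {out}")
    dilute = df[df.system == "dilute"].iloc[0]
    conc = df[df.system == "concentrated"].iloc[0]
    print("crowding ordering (concentrated vs dilute): "
          f"xanthine neighbors {conc.mean_xan_neighbors} > "
          f"{dilute.mean_xan_neighbors}; waters {conc.mean_waters} < "
          f"{dilute.mean_waters}")


if __name__ == "__main__":
    main()
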
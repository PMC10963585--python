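"""One-time calibration check of the hepatocyte kinetic defaults.

The cell-scale rate constants are not literature values; they are chosen so
that the standard verification conditions reproduce the expected zonation:

* inflow FFA 3 mmol/l, O2 0.091 mmol/l  -> pericentral steatosis,
* inflow FFA 0.2 mmol/l, O2 0.091 mmol/l -> periportal steatosis,

on the default single lobule, and so that the outflow-obstruction scenario
moves the obstructed lobule's pattern toward periportal.  Run this script to
re-verify the shipped defaults, or pass --scan to explore a small grid
around them (takes a few minutes).

Usage:  python scripts/calibrate_kinetics.py [--scan]
"""

import argparse
import itertools

import lobulefem as lf
from lobulefem.cell import KineticParams
from lobulefem.scenarios import obstructed_lobule_index


def zone_ratio(result, lobule=-1):
    df = result.zone_df
    last = df[(df["t"] == df["t"].max()) & (df["lobule"] == lobule)]
    m1 = float(last[last["zone"] == 1]["mean_n_T"].iloc[0])
    m3 = float(last[last["zone"] == 3]["mean_n_T"].iloc[0])
    return m3 / m1


def evaluate(kinetics: KineticParams, verbose=True):
    rows = {}
    for label, ffa in (("pericentral", 3.0), ("periportal", 0.2)):
        cfg = lf.ScenarioConfig(inflow_conc={"FFA": ffa, "Ox": 0.091},
                                kinetics=kinetics)
        res = lf.run_scenario(cfg)
        rows[label] = (zone_ratio(res), lf.classify_zonation(res))
    cfg = lf.ScenarioConfig(geometry="group7", bc_preset="outflow_obstruction",
                            target_edge_length=cfg.circumradius / 8,
                            kinetics=kinetics)
    res = lf.run_scenario(cfg)
    obs = obstructed_lobule_index(res.mesh)
    healthy = [li for li in range(res.mesh.n_lobules()) if li != obs]
    h_ratio = sum(zone_ratio(res, li) for li in healthy) / len(healthy)
    rows["obstructed"] = (zone_ratio(res, obs),
                          lf.classify_zonation(res, lobule=obs))
    rows["healthy_mean"] = (h_ratio, "")
    if verbose:
        for k, (r, cls) in rows.items():
            print(f"  {k:14s} zone3/zone1 = {r:6.3f}  {cls}")
    return rows


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scan", action="store_true",
                    help="scan a small grid around the defaults")
    args = ap.parse_args()

    print("shipped defaults:")
    base = KineticParams()
    evaluate(base)

    if args.scan:
        for vmax, km in itertools.product((0.9e-4, 1.05e-4, 1.2e-4),
                                          (0.25, 0.35, 0.5)):
            print(f"vmax_FFA={vmax:g}, KM_FFA={km:g}:")
            evaluate(base.replace(vmax_FFA=vmax, KM_FFA=km))


if __name__ == "__main__":
    main()
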
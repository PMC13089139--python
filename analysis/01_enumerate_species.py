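"""Enumerate the reaction species and the constraint sets they imply.

The isopimarenyl cation (A) carries five abstractable protons on the three
carbons flanking C8 — two each on C7 and C14 and one on C9 — which collapse
onto three possible olefins (7, 8, 10).  Crossed with the two pyrophosphate
anchor points this yields the ten constraint sets of the deprotonation scan.
"""

import json
from pathlib import Path

from carbdock import constraints as ct
from carbdock import intermediates as im
from carbdock import pipeline as pl
from carbdock import synthetic_data as sd

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    summary = {}
    for key in ("A", "B"):
        g = im.load_species(key)
        sites = im.enumerate_deprotonation_sites(g)
        products = im.enumerate_olefin_products(g, sites)
        per_carbon = {}
        for s in sites:
            per_carbon.setdefault(g.name(s.carbon), []).append(
                g.name(s.hydrogen))
        summary[key] = {
            "n_atoms": g.n_atoms,
            "cation_center": g.name(g.cation_center),
            "sites_per_carbon": {c: len(h) for c, h in per_carbon.items()},
            "n_sites": len(sites),
            "products": sorted({p.product_id for p in products.values()}),
        }
        print(f"species {key}: cation at {g.name(g.cation_center)}, "
              f"{len(sites)} deprotonation sites "
              f"{summary[key]['sites_per_carbon']}, products "
              f"{summary[key]['products']}")

    ws = sd.make_aligned_workspace(sd.FixtureSpec(seed=3), variant="T")
    g_a = im.load_species("A")
    sites = im.enumerate_deprotonation_sites(g_a)
    sets = ct.build_deprotonation_sets(
        g_a, sites, pl.BASE_SELECTOR, ws.receptor.anchor_selectors())
    summary["depro_scan_constraint_sets"] = [cs.set_id for cs in sets]
    print(f"\ndeprotonation scan: {len(sets)} constraint sets "
          f"(5 protons x 2 pyrophosphate anchors)")

    (RESULTS / "enumeration.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    ct.write_constraint_text(sets, RESULTS / "depro_constraint_sets.txt")
    Path(RESULTS / "species_registry.json").write_text(im.registry_to_json())
    print(f"wrote {RESULTS / 'enumeration.json'}")


if __name__ == "__main__":
    main()
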
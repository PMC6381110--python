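#!/usr/bin/env python
"""Accessible-lipid accounting for the bench assay recipes.

Tabulates the standard liposome recipes (binding, transport, kinetic and
membrane-association assays) and the accessible concentration of each doped
species.  The sterol pool counts both leaflets (fast flip-flop); the
phosphoinositide/probe pools count the outer leaflet only.  Writes
results/assay_compositions.csv.
"""

from pathlib import Path

import pandas as pd

from sterolex.composition import (
    LipidSpecies,
    LiposomeComposition,
    accessible_concentration,
    lipid_to_protein_ratio,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

DHE = LipidSpecies("DHE", 1.0, "cargo")
PIP = LipidSpecies("PI34P2", 0.5, "doped_pip")
DNS = LipidSpecies("DNS-PE", 0.5, "fret_probe")

RECIPES = {
    "dhe_binding (150 uM, 2.5% DNS-PE, 2% DHE)": LiposomeComposition.from_doping(
        150.0, [(DNS, 2.5), (DHE, 2.0)]
    ),
    "pip_binding (150 uM, 4% PIP)": LiposomeComposition.from_doping(150.0, [(PIP, 4.0)]),
    "dhe_transport donor (200 uM, 2.5% DNS-PE, 5% DHE)": LiposomeComposition.from_doping(
        200.0, [(DNS, 2.5), (DHE, 5.0)]
    ),
    "kinetic assay donor (200 uM, 5% DHE, 4% PIP)": LiposomeComposition.from_doping(
        200.0, [(DNS, 2.5), (DHE, 5.0), (PIP, 4.0)]
    ),
    "pip_transport donor (200 uM, 4% PIP)": LiposomeComposition.from_doping(
        200.0, [(PIP, 4.0)]
    ),
    "association assay (1 mM, 0.5% DHE)": LiposomeComposition.from_doping(
        1000.0, [(DHE, 0.5)]
    ),
}


def main() -> None:
    rows = []
    for label, comp in RECIPES.items():
        for species, frac in comp.components:
            if species.role == "structural":
                continue
            rows.append(
                {
                    "recipe": label,
                    "species": species.name,
                    "mole_percent": 100.0 * frac,
                    "accessible_fraction": species.accessible_fraction,
                    "accessible_uM": accessible_concentration(comp, species.name),
                }
            )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "assay_compositions.csv", index=False)
    print(table.to_string(index=False))
    assoc = RECIPES["association assay (1 mM, 0.5% DHE)"]
    ratio = lipid_to_protein_ratio(accessible_concentration(assoc, "DHE"), 1.0)
    print(f"\nassociation assay doped-lipid : protein ratio = {ratio:g} : 1")
    print("key pools: 10 uM DHE (kinetic/transport), 4 uM PIP (transport), "
          "3 uM PIP (binding at 150 uM)")


if __name__ == "__main__":
    main()
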